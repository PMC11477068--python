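"""Variant filters, region annotation, variation ratios, t-test."""

import numpy as np
import pytest

from m6avar import variants as vm
from m6avar.models import GeneModel, MethylSite, Variant

import oracles


def var(chrom="chr1", pos=10, ref="A", alt="G", gt="0/1", depth=None, source="DNA"):
    return Variant(chrom, pos, ref, alt, gt, depth, source)


class TestDnaFilter:
    def test_listed_position_kept_unlisted_dropped(self):
        kept = vm.filter_dna_variants([var(pos=5), var(pos=9)], {("chr1", 5)})
        assert [v.pos for v in kept] == [5]

    def test_no_dbsnp_passes_through(self):
        vs = [var(pos=5)]
        assert vm.filter_dna_variants(vs, None) == vs

    def test_matches_brute_force_membership(self, study):
        kept = vm.filter_dna_variants(study.dna_variants, study.dbsnp)
        expected = [v for v in study.dna_variants if (v.chrom, v.pos) in study.dbsnp]
        assert kept == expected


class TestRnaFilter:
    def test_strictly_greater_than_cutoff(self):
        kept = vm.filter_rna_variants(
            [var(depth=31, source="RNA"), var(pos=11, depth=30, source="RNA")], 30
        )
        assert [v.depth for v in kept] == [31]

    def test_min_depth_zero_keeps_depth_one(self):
        assert len(vm.filter_rna_variants([var(depth=1, source="RNA")], 0)) == 1

    def test_missing_depth_dropped(self):
        assert vm.filter_rna_variants([var(depth=None, source="RNA")], 30) == []


class TestRegionAnnotation:
    @pytest.fixture()
    def genes(self):
        return [
            GeneModel(
                "g1", "chr1", "+", 0, 1000,
                exons=((0, 200), (800, 1000)),
                utrs=((0, 50, "5UTR"),),
            )
        ]

    def test_utr_beats_exon(self, genes):
        assert vm.annotate_regions([var(pos=25)], genes)[0] == [("g1", "UTR")]

    def test_gene_body_outside_exons_is_intron(self, genes):
        assert vm.annotate_regions([var(pos=500)], genes)[0] == [("g1", "intron")]

    def test_outside_gene_bodies_is_intergenic(self, genes):
        assert vm.annotate_regions([var(pos=5000)], genes)[0] == [(None, "intergenic")]

    def test_label_fractions_sum_to_one(self, study):
        dist = vm.region_distribution(study.dna_variants, study.genes)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_matches_brute_force_labeling(self, study):
        subset = study.dna_variants[::11]
        got = vm.annotate_regions(subset, study.genes)
        for v, assignment in zip(subset, got):
            assert sorted(assignment) == sorted(
                oracles.region_labels(study.genes, v.chrom, v.pos)
            )


class TestGeneVariation:
    def test_ratio_arithmetic(self):
        gene = GeneModel("g1", "chr1", "+", 0, 3000)
        gv = vm.gene_variation([gene], [var(pos=p) for p in (10, 20, 30)])
        assert gv[0].variation_ratio == pytest.approx(0.001)

    def test_gene_without_variants_still_emitted(self):
        gene = GeneModel("g1", "chr1", "+", 0, 100)
        (gv,) = vm.gene_variation([gene], [])
        assert gv.n_var == 0 and gv.variation_ratio == 0.0

    def test_partition_and_counts_match_brute_force(self, study):
        gvs = vm.gene_variation(study.genes, study.dna_variants)
        by_gene = {g.gene_id: g for g in study.genes}
        for gv in gvs:
            assert gv.n_AT + gv.n_CG == gv.n_var  # partition conservation
            g = by_gene[gv.gene_id]
            expected = sum(
                1 for v in study.dna_variants
                if v.chrom == g.chrom and g.start <= v.pos < g.end
            )
            assert gv.n_var == expected


class TestMethylatedVariation:
    def test_plus_site_flags_ref_a(self):
        sites = [MethylSite("chr1", 10, "+", 40)]
        (v,) = vm.methylated_variation([var(pos=10, ref="A")], sites)
        assert v.m6a_overlap

    def test_minus_site_flags_ref_t(self):
        sites = [MethylSite("chr1", 10, "-", 40)]
        (v,) = vm.methylated_variation([var(pos=10, ref="T", alt="C")], sites)
        assert v.m6a_overlap

    def test_discordant_ref_not_flagged_but_logged(self, caplog):
        sites = [MethylSite("chr1", 10, "+", 40)]
        with caplog.at_level("WARNING"):
            (v,) = vm.methylated_variation([var(pos=10, ref="C", alt="G")], sites)
        assert not v.m6a_overlap
        assert "inconsistent site" in caplog.text

    def test_positional_mode_ignores_base(self):
        sites = [MethylSite("chr1", 10, "+", 40)]
        (v,) = vm.methylated_variation(
            [var(pos=10, ref="C", alt="G")], sites, require_base_concordance=False
        )
        assert v.m6a_overlap

    def test_flagged_ref_always_a_or_t(self, study):
        flagged = vm.methylated_variation(study.dna_variants, study.sites)
        assert all(v.ref in "AT" for v in flagged if v.m6a_overlap)


class TestAMutatedRatio:
    def test_ratio_arithmetic(self):
        # 10 modified A (1 mutated), 100 unmodified A (20 mutated)
        genome = {"chr1": "A" * 110 + "C" * 10}
        gene = GeneModel("g1", "chr1", "+", 0, 120)
        sites = [MethylSite("chr1", p, "+", 40) for p in range(10)]
        variants = [var(pos=0)] + [var(pos=p) for p in range(10, 30)]
        mod, unmod = vm.a_mutated_ratio(gene, sites, variants, genome)
        assert mod == pytest.approx(0.1)
        assert unmod == pytest.approx(0.2)

    def test_no_sites_gives_undefined_modified_ratio(self):
        genome = {"chr1": "A" * 100}
        gene = GeneModel("g1", "chr1", "+", 0, 100)
        mod, unmod = vm.a_mutated_ratio(gene, [], [var(pos=3)], genome)
        assert mod is None and unmod == pytest.approx(0.01)

    def test_matches_per_adenine_classification(self, study):
        for gene in study.genes[:20]:
            mod, unmod = vm.a_mutated_ratio(
                gene, study.sites, study.dna_variants, study.genome
            )
            coding = "A" if gene.strand == "+" else "T"
            site_pos = {
                s.pos for s in study.sites
                if s.chrom == gene.chrom and s.strand == gene.strand
                and gene.start <= s.pos < gene.end
            }
            a_pos = {
                i for i in range(gene.start, gene.end)
                if study.genome[gene.chrom][i] == coding
            }
            var_pos = {
                v.pos for v in study.dna_variants
                if v.chrom == gene.chrom and gene.start <= v.pos < gene.end
                and v.ref == coding
            }
            if site_pos:
                assert mod == pytest.approx(len(var_pos & site_pos) / len(site_pos))
            else:
                assert mod is None
            unmod_a = a_pos - site_pos
            if unmod_a:
                assert unmod == pytest.approx(len(var_pos - site_pos) / len(unmod_a))


class TestGroupComparison:
    def test_identical_constant_groups(self):
        res = vm.group_ratio_comparison([1.0, 1.0], [1.0, 1.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_large_shift_gives_tiny_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 200)
        res = vm.group_ratio_comparison(a + 5.0, a)
        assert res.p_value < 1e-12

    def test_matches_textbook_student_formula(self):
        rng = np.random.default_rng(3)
        a = list(rng.normal(0.0, 1.0, 30))
        b = list(rng.normal(0.3, 1.2, 25))
        res = vm.group_ratio_comparison(a, b)
        t, df, p = oracles.student_t(a, b)
        assert res.statistic == pytest.approx(t, rel=1e-10)
        assert res.df == df
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_welch_option_changes_df(self):
        a = [0.0, 1.0, 2.0, 3.0]
        b = [0.0, 10.0, 20.0, 30.0, 40.0]
        student = vm.group_ratio_comparison(a, b, equal_var=True)
        welch = vm.group_ratio_comparison(a, b, equal_var=False)
        assert student.df == 7
        assert welch.df != student.df


class TestRegionLengths:
    def test_precedence_partition_covers_gene(self, study):
        for gene in study.genes[:30]:
            lengths = vm.gene_region_lengths(gene)
            assert sum(lengths.values()) == gene.length
            assert min(lengths.values()) >= 0
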
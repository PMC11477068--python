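"""Depth filtering, density arithmetic, strand-aware gene methylation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from m6avar import methylome
from m6avar.models import DepthThresholds, GeneModel, MethylSite

import oracles


def site(chrom="chr1", pos=10, strand="+", cov=50):
    return MethylSite(chrom, pos, strand, cov)


class TestFilterByDepth:
    def test_below_autosome_cutoff_removed(self):
        thr = DepthThresholds(30, 15)
        assert methylome.filter_by_depth([site(cov=29)], thr, {"chrX"}) == []

    def test_boundary_coverage_kept(self):
        # only "less than" the cutoff is removed, so equality survives
        thr = DepthThresholds(30, 15)
        kept = methylome.filter_by_depth(
            [site(cov=30), site(chrom="chrX", cov=15)], thr, {"chrX"}
        )
        assert len(kept) == 2

    def test_zero_thresholds_are_identity(self, study):
        thr = DepthThresholds(0, 0)
        assert methylome.filter_by_depth(study.sites, thr, set()) == sorted(study.sites)

    @given(st.lists(st.tuples(st.integers(0, 100), st.integers(0, 80)), max_size=30))
    def test_filtering_is_idempotent(self, pairs):
        sites = [site(pos=p, cov=c) for p, c in dict(pairs).items()]
        thr = DepthThresholds(37, 18)
        once = methylome.filter_by_depth(sites, thr, set())
        assert methylome.filter_by_depth(once, thr, set()) == once


class TestDensity:
    def test_genome_density_arithmetic(self):
        genome = {"chr1": "AT" * 500}  # 1000 adenine positions over both strands
        sites = [site(pos=0), site(pos=2)]
        assert methylome.genome_density(sites, genome) == pytest.approx(0.002)

    def test_no_sites_gives_zero(self):
        assert methylome.genome_density([], {"chr1": "ACGT" * 10}) == 0.0

    def test_genome_without_adenines_is_error(self):
        with pytest.raises(ValueError):
            methylome.genome_density([site()], {"chr1": "GC" * 10})

    def test_per_chromosome_restriction_and_conservation(self, study):
        per_chrom = methylome.per_chromosome_density(study.sites, study.genome)
        total_a = {
            c: seq.count("A") + seq.count("T") for c, seq in study.genome.items()
        }
        weighted = sum(per_chrom[c] * total_a[c] for c in per_chrom) / sum(total_a.values())
        assert weighted == pytest.approx(methylome.genome_density(study.sites, study.genome))

    def test_chromosome_without_sites_reports_zero(self):
        genome = {"chr1": "AAAA", "chr2": "AAAA"}
        per_chrom = methylome.per_chromosome_density([site(pos=1)], genome)
        assert per_chrom["chr2"] == 0.0 and per_chrom["chr1"] > 0


class TestGeneMethylation:
    def test_only_same_strand_sites_count(self):
        genome = {"chr1": "A" * 100}
        gene = GeneModel("g1", "chr1", "+", 0, 100)
        sites = [site(pos=10, strand="+"), site(pos=20, strand="-")]
        (gm,) = methylome.gene_methylation([gene], sites, genome)
        assert gm.n_6mA == 1 and gm.methylated

    def test_minus_strand_gene_counts_plus_strand_ts(self):
        genome = {"chr1": "T" * 50 + "A" * 50}
        gene = GeneModel("g1", "chr1", "-", 0, 100)
        (gm,) = methylome.gene_methylation([gene], [site(pos=5, strand="-")], genome)
        assert gm.n_A == 50 and gm.n_6mA == 1

    def test_gene_without_coding_adenines_flagged(self, caplog):
        genome = {"chr1": "GC" * 50}
        gene = GeneModel("g1", "chr1", "+", 0, 100)
        with caplog.at_level("WARNING"):
            (gm,) = methylome.gene_methylation([gene], [], genome)
        assert gm.zero_adenine and gm.density == 0.0 and not gm.methylated

    def test_matches_brute_force_on_synthetic_study(self, study):
        filtered = methylome.filter_by_depth(
            study.sites, study.params.depth_thresholds, {study.params.sex_chrom_name}
        )
        result = methylome.gene_methylation(study.genes, filtered, study.genome)
        expected = oracles.gene_site_counts(study.genes, filtered)
        for gm in result:
            assert gm.n_6mA == expected[gm.gene_id]
        subset = study.genes[::37]
        for g in subset:
            gm = next(m for m in result if m.gene_id == g.gene_id)
            assert gm.n_A == oracles.coding_adenines(g, study.genome)


class TestMethylociSummary:
    def test_on_gene_percentage_toy(self):
        genes = [GeneModel("g1", "chr1", "+", 0, 100)]
        sites = [site(pos=10), site(pos=150), site(pos=50, strand="-"), site(pos=200)]
        s = methylome.methyloci_on_gene_summary(sites, genes)
        assert (s.n_total, s.n_on_gene, s.pct_on_gene) == (4, 2, 50.0)
        assert s.n_methylated_genes == 1  # the minus-strand site doesn't methylate g1

    def test_all_intergenic_gives_zero_pct(self):
        genes = [GeneModel("g1", "chr1", "+", 0, 10)]
        s = methylome.methyloci_on_gene_summary([site(pos=50)], genes)
        assert s.pct_on_gene == 0.0

    def test_no_sites_is_error(self):
        with pytest.raises(ValueError):
            methylome.methyloci_on_gene_summary([], [])

    def test_matches_brute_force_membership(self, study):
        s = methylome.methyloci_on_gene_summary(study.sites, study.genes)
        assert s.n_on_gene == oracles.on_gene_site_count(study.sites, study.genes)


class TestSharedGenes:
    def test_identical_sets_all_hundred_percent(self):
        sets = {"a": {"g1", "g2"}, "b": {"g1", "g2"}}
        rep = methylome.shared_gene_summary(sets)
        assert rep.pct_shared("a", ["a", "b"]) == 100.0

    def test_disjoint_sets_zero_intersections(self):
        rep = methylome.shared_gene_summary({"a": {"g1"}, "b": {"g2"}, "c": {"g3"}})
        assert all(v == 0 for v in rep.intersections.values())

    def test_empty_sample_percentage_undefined(self):
        rep = methylome.shared_gene_summary({"a": set(), "b": {"g1"}})
        assert rep.pct_shared("a", ["a", "b"]) is None


class TestConsistentSites:
    def test_identity_and_disjoint(self):
        sites = [site(pos=1), site(pos=2)]
        assert methylome.consistent_sites(sites, sites) == sorted(sites)
        assert methylome.consistent_sites(sites, [site(pos=9)]) == []

    def test_coverage_is_minimum_of_samples(self):
        a = [site(pos=1, cov=50)]
        b = [site(pos=1, cov=33)]
        assert methylome.consistent_sites(a, b)[0].coverage == 33

    def test_matches_brute_force_intersection(self, study):
        a = study.sites[::2]
        b = study.sites[::3]
        got = methylome.consistent_sites(a, b)
        assert [s.key for s in got] == oracles.intersect_sites(a, b)


class TestDensityCorrelation:
    def test_linear_scaling_gives_one(self):
        a = {"chr1": 0.1, "chr2": 0.2, "chr3": 0.4}
        b = {c: 2 * v for c, v in a.items()}
        assert methylome.density_correlation(a, b) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        a = {"chr1": 0.1, "chr2": 0.2, "chr3": 0.4}
        b = {c: -v for c, v in a.items()}
        assert methylome.density_correlation(a, b) == pytest.approx(-1.0)

    def test_self_correlation_is_one(self, study):
        per_chrom = methylome.per_chromosome_density(study.sites, study.genome)
        assert methylome.density_correlation(per_chrom, per_chrom) == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        a = {"chr1": 0.1, "chr2": 0.1, "chr3": 0.1}
        b = {"chr1": 0.1, "chr2": 0.2, "chr3": 0.3}
        assert methylome.density_correlation(a, b) is None

    def test_matches_textbook_formula(self):
        import numpy as np

        rng = np.random.default_rng(5)
        a = {f"chr{i}": float(v) for i, v in enumerate(rng.random(8))}
        b = {f"chr{i}": float(v) for i, v in enumerate(rng.random(8))}
        keys = sorted(a)
        expected = oracles.pearson_r([a[k] for k in keys], [b[k] for k in keys])
        assert methylome.density_correlation(a, b) == pytest.approx(expected, abs=1e-12)


class TestMotifContexts:
    def test_plus_strand_window(self):
        genome = {"chr1": "CCCCCCCCCCACCCCCCCCC"}
        (rec,) = methylome.export_motif_contexts([site(pos=10)], genome, flank=2)
        assert rec[1] == "CCACC"

    def test_minus_strand_center_is_adenine(self):
        genome = {"chr1": "GGGGGTGGGG"}  # T at pos 5 = adenine on minus strand
        (rec,) = methylome.export_motif_contexts([site(pos=5, strand="-")], genome, flank=2)
        assert rec[1][2] == "A"

    def test_sites_near_contig_end_skipped(self, caplog):
        genome = {"chr1": "AAAAAAAA"}
        with caplog.at_level("WARNING"):
            recs = methylome.export_motif_contexts([site(pos=0), site(pos=4)], genome, 3)
        assert len(recs) == 1

    def test_planted_motifs_recovered(self, study):
        """All exported centers are A; planted AGGYR contexts are visible."""
        import re

        genic = [
            s for g in study.genes
            for s in study.sites
            if s.chrom == g.chrom and s.strand == g.strand and g.start <= s.pos < g.end
        ]
        flank = 4
        recs = methylome.export_motif_contexts(genic, study.genome, flank)
        assert all(seq[flank] == "A" for _n, seq in recs)
        n_motif = sum(
            bool(re.match("AGG[CT][AG]", seq[flank:])) for _n, seq in recs
        )
        # p_motif = 0.7 with a few skipped plantings; well over half should match
        assert n_motif / len(recs) > 0.5
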
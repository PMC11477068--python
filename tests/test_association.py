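"""Regression fits, dropped-term handling, imprinting contrasts."""

import math

import numpy as np
import pytest

from m6avar import association, simulate
from m6avar.models import TRANSMIT_TYPES, GeneFeatureRow

import oracles


def row(i, methylated, x=None, density=None, n_var=0, imprinted=False):
    return GeneFeatureRow(
        gene_id=f"g{i:04d}",
        y_density=density if density is not None else (0.01 if methylated else 0.0),
        methylated=methylated,
        x=dict(x or {}),
        n_var_dna=n_var,
        imprinted=imprinted,
    )


class TestLogistic:
    def test_all_zero_covariates_give_closed_form_intercept(self):
        rows = [row(i, i < 3) for i in range(10)]  # 3 methylated of 10
        res = association.fit_logistic(rows)
        assert res.term_names == ["(Intercept)"]
        assert res.term("(Intercept)").coefficient == pytest.approx(math.log(3 / 7), abs=1e-6)
        assert len(res.dropped_terms) == 6

    def test_duplicated_covariate_dropped_as_collinear(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            k = int(rng.poisson(2))
            rows.append(row(i, bool(rng.random() < 0.5), {"0/1_0/1": k, "0/1_1/1": k}))
        res = association.fit_logistic(rows)
        dropped = dict(res.dropped_terms)
        assert dropped.get("0/1_1/1") == "collinear with retained columns"
        assert "0/1_0/1" in res.term_names

    def test_single_class_response_is_error(self):
        with pytest.raises(ValueError):
            association.fit_logistic([row(i, True) for i in range(5)])

    def test_complete_separation_reported_with_covariate_name(self):
        rows = [row(i, i < 50, {"0/1_0/1": 5 if i < 50 else 0}) for i in range(100)]
        with pytest.raises(association.SeparationError, match="0/1_0/1"):
            association.fit_logistic(rows)

    def test_permutation_invariance(self):
        rows = simulate.simulate_logistic_rows(n=400, seed=3)
        res1 = association.fit_logistic(rows)
        res2 = association.fit_logistic(list(reversed(rows)))
        for t1, t2 in zip(res1.terms, res2.terms):
            assert t1.coefficient == pytest.approx(t2.coefficient, rel=1e-9)
            assert t1.p_value == pytest.approx(t2.p_value, rel=1e-9)

    def test_agrees_with_independent_irls(self):
        """statsmodels path matches hand-rolled Newton IRLS on random fixtures."""
        seeds = np.random.SeedSequence(17).generate_state(20)
        for seed in seeds:
            rows = simulate.simulate_logistic_rows(n=150, seed=int(seed) % 2**31)
            try:
                res = association.fit_logistic(rows)
            except association.SeparationError:
                continue  # small-n fixtures can separate; not this test's concern
            X = np.array([r.x_vector() for r in rows], dtype=float)
            keep = [j for j, t in enumerate(TRANSMIT_TYPES) if t in res.term_names]
            Xd = np.column_stack([np.ones(len(rows)), X[:, keep]])
            y = np.array([float(r.methylated) for r in rows])
            beta, se = oracles.irls_logistic(Xd, y)
            got = np.array([t.coefficient for t in res.terms])
            assert np.allclose(got, beta, rtol=1e-6)
            assert np.allclose([t.std_error for t in res.terms], se, rtol=1e-5)


class TestLinear:
    def test_constant_response_degenerate_fit(self):
        rows = [row(i, True, {"0/1_0/1": i % 4}, density=0.02) for i in range(30)]
        res = association.fit_linear(rows)
        assert res.term("(Intercept)").coefficient == pytest.approx(0.02)
        assert all(t.coefficient == 0 for t in res.terms[1:])

    def test_noiseless_exact_recovery(self):
        rows = [
            row(i, True, {"0/1_0/0": i % 5}, density=1e-4 + 5e-4 * (i % 5))
            for i in range(40)
        ]
        res = association.fit_linear(rows)
        assert res.term("(Intercept)").coefficient == pytest.approx(1e-4, rel=1e-8)
        assert res.term("0/1_0/0").coefficient == pytest.approx(5e-4, rel=1e-8)

    def test_unmethylated_rows_ignored(self):
        rows = [row(i, True, {"0/1_0/0": 1}, density=0.01) for i in range(20)]
        rows += [row(100 + i, False) for i in range(20)]
        res = association.fit_linear(rows)
        assert res.n_obs == 20

    def test_agrees_with_normal_equations(self):
        seeds = np.random.SeedSequence(23).generate_state(20)
        for seed in seeds:
            rows = simulate.simulate_linear_rows(n=120, seed=int(seed) % 2**31)
            res = association.fit_linear(rows)
            X = np.array([r.x_vector() for r in rows], dtype=float)
            keep = [j for j, t in enumerate(TRANSMIT_TYPES) if t in res.term_names]
            Xd = np.column_stack([np.ones(len(rows)), X[:, keep]])
            y = np.array([r.y_density for r in rows])
            beta, se = oracles.ols_normal_equations(Xd, y)
            assert np.allclose([t.coefficient for t in res.terms], beta, rtol=1e-8)
            assert np.allclose([t.std_error for t in res.terms], se, rtol=1e-8)

    def test_single_seed_recovery_within_two_se(self):
        rows = simulate.simulate_linear_rows(n=5000, seed=1243502527)
        res = association.fit_linear(rows)
        t = res.term("0/1_0/0")
        assert abs(t.coefficient - 4.7e-4) <= 2 * t.std_error
        assert t.p_value < 0.01


class TestImprintingContrasts:
    def _rows(self, spec):
        out = []
        for i, (meth, imp, n_var) in enumerate(spec):
            out.append(row(i, meth, n_var=n_var, imprinted=imp))
        return out

    def test_identical_constant_groups_p_one(self):
        spec = [(m, i, 5) for m in (True, False) for i in (True, False) for _ in range(3)]
        contrasts = association.imprinting_contrasts(self._rows(spec))
        for _name, p in contrasts.as_table():
            assert p == 1.0

    def test_methylated_lower_counts_detected_with_direction(self):
        rng = np.random.default_rng(4)
        spec = []
        for _ in range(150):
            for imp in (True, False):
                spec.append((True, imp, int(rng.poisson(2))))
                spec.append((False, imp, int(rng.poisson(8))))
        contrasts = association.imprinting_contrasts(self._rows(spec))
        c = contrasts.methylated_vs_un_within_non_imprinted
        assert c.p_value < 1e-6
        assert c.mean_a < c.mean_b  # methylated genes carry fewer variants

    def test_empty_cell_reported_not_computable(self):
        spec = [(True, False, 3)] * 5 + [(False, False, 4)] * 5
        contrasts = association.imprinting_contrasts(self._rows(spec))
        assert contrasts.imprinted_vs_non_within_methylated is None
        assert contrasts.methylated_vs_un_within_non_imprinted is not None

    def test_explicit_id_set_overrides_row_flags(self):
        spec = [(m, False, 3 + m) for m in (True, False) for _ in range(4)]
        rows = self._rows(spec)
        ids = {rows[0].gene_id, rows[4].gene_id}
        contrasts = association.imprinting_contrasts(rows, imprinted_ids=ids)
        assert contrasts.cell_sizes["methylated_imprinted"] >= 1


class TestFeatureRowAssembly:
    def test_rows_built_from_study_summaries(self, study):
        from m6avar import methylome, transmission
        from m6avar import variants as vm

        filtered = methylome.filter_by_depth(
            study.sites, study.params.depth_thresholds, {study.params.sex_chrom_name}
        )
        gm = methylome.gene_methylation(study.genes, filtered, study.genome)
        gv = vm.gene_variation(study.genes, study.dna_variants)
        res = transmission.join_dna_rna(
            study.dna_variants, study.rna_variants, study.rna_coverage
        )
        counts = transmission.gene_transmit_counts(res.records, study.genes)
        rows = association.build_feature_rows(gm, gv, counts, study.imprinted_ids)
        assert len(rows) == len(study.genes)
        by_id = {r.gene_id: r for r in rows}
        for g in study.genes[:25]:
            truth = study.truth.genes[g.gene_id]
            assert by_id[g.gene_id].methylated == truth.methylated
            assert by_id[g.gene_id].n_var_dna == truth.n_var
            assert by_id[g.gene_id].imprinted == truth.imprinted
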
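"""Regression models linking 6mA methylation to transmit-type counts,
plus the imprinting-gene contrasts.

Two models are fitted on per-gene feature rows:

* **logistic** — ``logit(p) = b0 + sum_n b_n x_n``, where p is the
  probability that a gene is methylated and x_1..x_6 are its six
  transmit-type counts. Which transmission classes predict methylation?
* **linear** — for methylated genes only, OLS of the 6mA density y on the
  same six counts: does methylation level scale with particular classes?

Covariates that are all zero or linearly dependent on already-kept columns
are dropped and reported, so sparse studies (where e.g. 1/1_0/0 hardly
occurs) yield the familiar four-term summary table. Inference is Wald;
no multiple-testing correction is applied by default, matching raw
summary-table reporting (a Benjamini-Hochberg helper is provided).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .models import (
    TRANSMIT_TYPES,
    ComparisonResult,
    GeneFeatureRow,
    GeneMethylation,
    GeneVariation,
    RegressionResult,
    TermEstimate,
)
from .variants import group_ratio_comparison

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Logistic fit abandoned because a covariate perfectly separates the classes."""


# ---------------------------------------------------------------------------
# Feature-row assembly
# ---------------------------------------------------------------------------

def build_feature_rows(
    methylation: Sequence[GeneMethylation],
    variation: Sequence[GeneVariation],
    transmit_counts: Mapping[str, Mapping[str, int]],
    imprinted_ids: Iterable[str] = (),
) -> list[GeneFeatureRow]:
    """Combine per-gene summaries into regression design rows.

    Every gene present in the methylation summary gets a row; missing
    transmit counts or variant counts default to zero.
    """
    imprinted = set(imprinted_ids)
    var_by_id = {v.gene_id: v for v in variation}
    rows = []
    for m in methylation:
        counts = transmit_counts.get(m.gene_id, {})
        v = var_by_id.get(m.gene_id)
        rows.append(
            GeneFeatureRow(
                gene_id=m.gene_id,
                y_density=m.density,
                methylated=m.methylated,
                x={t: int(counts.get(t, 0)) for t in TRANSMIT_TYPES},
                n_var_dna=v.n_var if v else 0,
                imprinted=m.gene_id in imprinted,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Design-matrix pruning
# ---------------------------------------------------------------------------

def _select_columns(
    X: np.ndarray, names: Sequence[str]
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Greedily keep covariates that add rank beyond the intercept."""
    n = X.shape[0]
    kept_cols = [np.ones(n)]
    kept_names: list[str] = []
    dropped: list[tuple[str, str]] = []
    for j, name in enumerate(names):
        col = X[:, j]
        if not np.any(col):
            dropped.append((name, "all zero"))
            continue
        trial = np.column_stack(kept_cols + [col])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept_cols.append(col)
            kept_names.append(name)
        else:
            dropped.append((name, "collinear with retained columns"))
    for name, reason in dropped:
        logger.info("dropping covariate %s (%s)", name, reason)
    return np.column_stack(kept_cols), kept_names, dropped


def _rows_to_design(rows: Sequence[GeneFeatureRow]) -> np.ndarray:
    return np.array([r.x_vector() for r in rows], dtype=float)


def _result_from_fit(
    model: str,
    params,
    bse,
    tvalues,
    pvalues,
    names: Sequence[str],
    n_obs: int,
    dropped: list[tuple[str, str]],
    residual_summary: float,
) -> RegressionResult:
    terms = [
        TermEstimate(
            name=name,
            coefficient=float(params[i]),
            std_error=float(bse[i]),
            statistic=float(tvalues[i]),
            p_value=float(min(max(pvalues[i], 0.0), 1.0)) if np.isfinite(pvalues[i]) else 1.0,
        )
        for i, name in enumerate(["(Intercept)"] + list(names))
    ]
    return RegressionResult(
        model=model, terms=terms, n_obs=n_obs,
        dropped_terms=dropped, residual_summary=float(residual_summary),
    )


# ---------------------------------------------------------------------------
# Logistic model
# ---------------------------------------------------------------------------

def fit_logistic(rows: Sequence[GeneFeatureRow]) -> RegressionResult:
    """ML logistic fit of the methylation flag on transmit-type counts.

    Deterministic given the rows (Newton IRLS, no randomness); permuting
    row order changes nothing. Raises :class:`SeparationError` on complete
    separation, naming the separating covariate when one covariate alone
    explains it, and ``ValueError`` when the response has a single class.
    """
    y = np.array([int(r.methylated) for r in rows], dtype=float)
    n1 = int(y.sum())
    if n1 < 2 or len(y) - n1 < 2:
        raise ValueError(
            f"logistic fit needs >=2 rows per response class (have {n1} methylated, "
            f"{len(y) - n1} unmethylated)"
        )
    X, kept_names, dropped = _select_columns(_rows_to_design(rows), TRANSMIT_TYPES)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"logistic fit failed: {_describe_separation(y, X, kept_names)} ({exc})"
        ) from exc
    if np.any(np.abs(res.params) > 30):
        raise SeparationError(
            "logistic fit diverged: " + _describe_separation(y, X, kept_names)
        )
    return _result_from_fit(
        "logistic", res.params, res.bse, res.tvalues, res.pvalues,
        kept_names, len(rows), dropped, residual_summary=float(res.llf * -2),
    )


def _describe_separation(y: np.ndarray, X: np.ndarray, names: Sequence[str]) -> str:
    for j, name in enumerate(names, start=1):
        col = X[:, j]
        lo1, hi1 = col[y == 1].min(), col[y == 1].max()
        lo0, hi0 = col[y == 0].min(), col[y == 0].max()
        if lo1 > hi0 or lo0 > hi1:
            return f"covariate {name} perfectly separates the response classes"
    return "perfect separation (no single separating covariate identified)"


# ---------------------------------------------------------------------------
# Linear model
# ---------------------------------------------------------------------------

def fit_linear(rows: Sequence[GeneFeatureRow]) -> RegressionResult:
    """OLS of 6mA density on transmit-type counts, methylated genes only.

    Unmethylated rows in the input are ignored (the model is defined on
    methylated genes). A zero-variance response is a degenerate fit: the
    intercept recovers the constant, slopes are 0, and p-values are
    reported as 1 with a logged warning.
    """
    rows = [r for r in rows if r.methylated]
    X_raw = _rows_to_design(rows)
    X, kept_names, dropped = _select_columns(X_raw, TRANSMIT_TYPES)
    if len(rows) < X.shape[1] + 1:
        raise ValueError(f"need >= {X.shape[1] + 1} methylated rows, have {len(rows)}")
    y = np.array([r.y_density for r in rows], dtype=float)
    if np.ptp(y) == 0:
        logger.warning("fit_linear: zero response variance; degenerate fit")
        params = np.zeros(X.shape[1])
        params[0] = y[0] if len(y) else 0.0
        zeros = np.zeros(X.shape[1])
        return _result_from_fit(
            "linear", params, zeros, zeros, np.ones(X.shape[1]),
            kept_names, len(rows), dropped, residual_summary=0.0,
        )
    res = sm.OLS(y, X).fit()
    with np.errstate(invalid="ignore"):
        pvals = np.where(np.isfinite(res.pvalues), res.pvalues, 1.0)
    return _result_from_fit(
        "linear", res.params, res.bse, res.tvalues, pvals,
        kept_names, len(rows), dropped,
        residual_summary=float(res.mse_resid) if res.df_resid > 0 else 0.0,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (optional; raw p-values are the default report)."""
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(p_values, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# Imprinting contrasts
# ---------------------------------------------------------------------------

@dataclass
class ImprintingContrasts:
    """The four 2x2-cell t-tests on per-gene DNA variant counts.

    Cells: genes split by methylation status and imprinting membership.
    ``None`` marks a comparison that was not computable (a cell with fewer
    than two genes).
    """

    imprinted_vs_non_within_methylated: Optional[ComparisonResult]
    imprinted_vs_non_within_unmethylated: Optional[ComparisonResult]
    methylated_vs_un_within_imprinted: Optional[ComparisonResult]
    methylated_vs_un_within_non_imprinted: Optional[ComparisonResult]
    cell_sizes: dict[str, int] = None

    def as_table(self) -> list[tuple[str, Optional[float]]]:
        return [
            ("imprinted_vs_non|methylated",
             self.imprinted_vs_non_within_methylated.p_value
             if self.imprinted_vs_non_within_methylated else None),
            ("imprinted_vs_non|unmethylated",
             self.imprinted_vs_non_within_unmethylated.p_value
             if self.imprinted_vs_non_within_unmethylated else None),
            ("methylated_vs_unmethylated|imprinted",
             self.methylated_vs_un_within_imprinted.p_value
             if self.methylated_vs_un_within_imprinted else None),
            ("methylated_vs_unmethylated|non_imprinted",
             self.methylated_vs_un_within_non_imprinted.p_value
             if self.methylated_vs_un_within_non_imprinted else None),
        ]


def imprinting_contrasts(
    rows: Sequence[GeneFeatureRow],
    imprinted_ids: Optional[set[str]] = None,
    equal_var: bool = True,
) -> ImprintingContrasts:
    """Compare DNA variant counts across the methylation x imprinting grid.

    When ``imprinted_ids`` is given it overrides the rows' own flags.
    Each of the four comparisons is a two-sided t-test on ``n_var_dna``.
    """
    def is_imprinted(r: GeneFeatureRow) -> bool:
        return r.gene_id in imprinted_ids if imprinted_ids is not None else r.imprinted

    cells: dict[tuple[bool, bool], list[float]] = {
        (m, i): [] for m in (True, False) for i in (True, False)
    }
    for r in rows:
        cells[(r.methylated, is_imprinted(r))].append(float(r.n_var_dna))

    def compare(a_key, b_key, name_a, name_b) -> Optional[ComparisonResult]:
        a, b = cells[a_key], cells[b_key]
        if len(a) < 2 or len(b) < 2:
            logger.warning("imprinting contrast %s vs %s not computable "
                           "(cell sizes %d, %d)", name_a, name_b, len(a), len(b))
            return None
        return group_ratio_comparison(a, b, name_a, name_b, equal_var=equal_var)

    sizes = {
        "methylated_imprinted": len(cells[(True, True)]),
        "methylated_non_imprinted": len(cells[(True, False)]),
        "unmethylated_imprinted": len(cells[(False, True)]),
        "unmethylated_non_imprinted": len(cells[(False, False)]),
    }
    return ImprintingContrasts(
        imprinted_vs_non_within_methylated=compare(
            (True, True), (True, False), "methylated-imprinted", "methylated-non-imprinted"),
        imprinted_vs_non_within_unmethylated=compare(
            (False, True), (False, False), "unmethylated-imprinted", "unmethylated-non-imprinted"),
        methylated_vs_un_within_imprinted=compare(
            (True, True), (False, True), "methylated-imprinted", "unmethylated-imprinted"),
        methylated_vs_un_within_non_imprinted=compare(
            (True, False), (False, False), "methylated-non-imprinted", "unmethylated-non-imprinted"),
        cell_sizes=sizes,
    )


def write_regression_tsv(result: RegressionResult, path: str) -> None:
    """Summary-table TSV: term, estimate, std error, statistic, p-value."""
    with open(path, "w") as fh:
        fh.write("term\testimate\tstd_error\tstatistic\tp_value\n")
        for t in result.terms:
            fh.write(
                f"{t.name}\t{t.coefficient:.6g}\t{t.std_error:.6g}\t"
                f"{t.statistic:.6g}\t{t.p_value:.6g}\n"
            )
        for name, reason in result.dropped_terms:
            fh.write(f"{name}\tNA\tNA\tNA\tNA\n")


def write_contrasts_tsv(contrasts: ImprintingContrasts, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("comparison\tp_value\n")
        for name, p in contrasts.as_table():
            fh.write(f"{name}\t{'NA' if p is None else f'{p:.6g}'}\n")
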
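"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — per-base scans, per-record loops,
textbook formulas — and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as _scipy_stats


def gene_site_counts(genes, sites):
    """Per-gene same-strand site count by scanning every site x gene pair."""
    counts = {g.gene_id: 0 for g in genes}
    for s in sites:
        for g in genes:
            if (
                g.chrom == s.chrom
                and g.strand == s.strand
                and g.start <= s.pos < g.end
            ):
                counts[g.gene_id] += 1
    return counts


def coding_adenines(gene, genome):
    base = "A" if gene.strand == "+" else "T"
    return sum(1 for i in range(gene.start, gene.end) if genome[gene.chrom][i] == base)


def on_gene_site_count(sites, genes):
    n = 0
    for s in sites:
        if any(g.chrom == s.chrom and g.start <= s.pos < g.end for g in genes):
            n += 1
    return n


def region_labels(genes, chrom, pos):
    """All (gene_id, label) pairs for a position, by scanning every gene."""
    out = []
    for g in genes:
        if g.chrom != chrom or not (g.start <= pos < g.end):
            continue
        if any(s <= pos < e for s, e, _t in g.utrs):
            label = "UTR"
        elif any(s <= pos < e for s, e in g.exons):
            label = "exon"
        else:
            label = "intron"
        out.append((g.gene_id, label))
    return out or [(None, "intergenic")]


def transmit_counts(records, genes, transmit_types):
    counts = {g.gene_id: {t: 0 for t in transmit_types} for g in genes}
    for r in records:
        for g in genes:
            if g.chrom == r.chrom and g.start <= r.pos < g.end:
                counts[g.gene_id][r.transmit_type] += 1
    return counts


def intersect_sites(sites_a, sites_b):
    keys = {(s.chrom, s.pos, s.strand) for s in sites_b}
    return sorted(
        (s.chrom, s.pos, s.strand) for s in sites_a if (s.chrom, s.pos, s.strand) in keys
    )


def intersect_events(recs_a, recs_b):
    keys = {(r.chrom, r.pos, r.ref, r.alt, r.transmit_type) for r in recs_b}
    return sorted(
        (r.chrom, r.pos, r.ref, r.alt, r.transmit_type)
        for r in recs_a
        if (r.chrom, r.pos, r.ref, r.alt, r.transmit_type) in keys
    )


def pearson_r(a, b):
    """Textbook product-moment correlation."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    return num / (da * db)


def student_t(a, b):
    """Pooled-variance two-sample t statistic, df and two-sided p."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * _scipy_stats.t.sf(abs(t), df)
    return t, df, p


def irls_logistic(X, y, tol=1e-10, max_iter=100):
    """Newton/IRLS logistic regression from first principles."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = p * (1.0 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov))


def ols_normal_equations(X, y):
    """OLS via the normal equations, with classical standard errors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    return beta, np.sqrt(np.diag(sigma2 * xtx_inv))
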
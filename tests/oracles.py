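"""Independent straight-line oracles for the test suite.

Everything here is deliberately written as naive per-element loops over
plain Python containers, independent of the pipeline's vectorized pandas
implementations, so agreement is evidence of correctness rather than of
shared code.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def oracle_cpm(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Per-column counts-per-million by an explicit loop."""
    out = np.empty(counts.shape, dtype=float)
    for j in range(counts.shape[1]):
        col = counts[:, j].astype(float) + pseudocount
        total = np.sum(col)
        for i in range(counts.shape[0]):
            out[i, j] = 1e6 * col[i] / total
    return out


def oracle_score_screen(
    counts,
    guide_genes: dict,
    comparisons: list,
    pseudocount: float = 0.5,
    control_min: int = 10,
    treated_min: int = 50,
    top_n: int = 2,
    nontargeting: str = "NONTARGETING",
):
    """Straight-line re-implementation of the whole scoring chain.

    ``counts``: dict sample_id -> dict guide_id -> int.
    ``comparisons``: list of (cell_line, screen_type, drug, replicate,
    treated_sample, control_sample).
    Returns (guide_min, gene_sums): guide_min maps
    (guide, cell_line, screen_type, drug) -> replicate-min L2FC (or None if
    fully filtered); gene_sums maps (gene, cell_line, screen_type, drug) ->
    L2FC sum (or None for <top_n surviving guides).
    """
    guides = list(next(iter(counts.values())).keys())
    # CPM per sample
    cpm = {}
    for sid, col in counts.items():
        total = np.sum(np.array([col[g] for g in guides], dtype=float) + pseudocount)
        cpm[sid] = {g: 1e6 * (col[g] + pseudocount) / total for g in guides}
    # per-comparison l2fc with AND filter
    per_guide: dict = {}
    for (cl, st, drug, rep, tid, cid) in comparisons:
        for g in guides:
            excluded = counts[cid][g] < control_min and counts[tid][g] < treated_min
            if excluded:
                continue
            val = np.log2(cpm[tid][g] / cpm[cid][g])
            per_guide.setdefault((g, cl, st, drug), []).append(val)
    guide_min = {}
    groups = {(cl, st, drug) for (cl, st, drug, *_ ) in comparisons}
    for g in guides:
        for (cl, st, drug) in groups:
            vals = per_guide.get((g, cl, st, drug))
            guide_min[(g, cl, st, drug)] = min(vals) if vals else None
    # gene L2FC sums
    gene_sums = {}
    genes = sorted({gn for gn in guide_genes.values() if gn != nontargeting})
    for gene in genes:
        gene_guides = sorted(g for g, gn in guide_genes.items() if gn == gene)
        for (cl, st, drug) in groups:
            surviving = [
                (guide_min[(g, cl, st, drug)], g)
                for g in gene_guides
                if guide_min[(g, cl, st, drug)] is not None
            ]
            if len(surviving) < top_n:
                gene_sums[(gene, cl, st, drug)] = None
                continue
            surviving.sort(key=lambda t: (-t[0], t[1]))
            total = surviving[0][0]
            for v, _ in surviving[1:top_n]:
                total = total + v
            gene_sums[(gene, cl, st, drug)] = total
    return guide_min, gene_sums


def oracle_top2_by_pairs(values: list) -> float:
    """Top-2 sum as the maximum pairwise sum over all guide pairs."""
    best = -np.inf
    for a, b in combinations(values, 2):
        best = max(best, a + b)
    return best


def exact_wilcoxon_greater(x, y) -> float:
    """Exact one-sided (greater) Mann-Whitney p by full enumeration.

    Enumerates all C(m+n, m) assignments of the pooled mid-ranks to the
    first sample; feasible for m + n <= 12.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    count = total = 0
    for comb in combinations(range(m + n), m):
        u = ranks[list(comb)].sum() - m * (m + 1) / 2
        count += u >= u_obs - 1e-12
        total += 1
    return count / total


def normal_approx_wilcoxon_greater(x, y) -> float:
    """Tie-corrected large-sample normal approximation (mid-ranks, no
    continuity correction) for the one-sided Mann-Whitney test."""
    from scipy.stats import norm, rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = ranks[:m].sum() - m * (m + 1) / 2
    mu = m * n / 2
    N = m + n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (N * (N - 1))
    var = m * n / 12 * (N + 1 - tie_term)
    return float(norm.sf((u - mu) / np.sqrt(var)))


def hand_logrank_2group(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square by explicit risk-set enumeration."""
    t = np.concatenate([times_a, times_b]).astype(float)
    e = np.concatenate([events_a, events_b]).astype(int)
    g = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))]).astype(int)
    o_minus_e = 0.0
    var = 0.0
    for tt in sorted(set(t[e == 1])):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & (g == 0)).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (g == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
    return float(o_minus_e**2 / var)


def quadrature_auc(viability_fn, dose_lo: float, dose_hi: float, n: int = 100001) -> float:
    """Fine-grid trapezoid quadrature of viability over log10 dose,
    normalized by the log-dose range."""
    x = np.linspace(np.log10(dose_lo), np.log10(dose_hi), n)
    y = np.array([viability_fn(10.0**xi) for xi in x])
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))
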
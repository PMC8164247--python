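"""Expression-weighted drug-sensitivity scoring (the PancDS predictor).

A sample's expected resistance to a drug is the sum, over genes, of the
gene's z-scored expression weighted by a screen-derived scalar (the
minimum L2FC sum of the gene across cell lines for that drug).  High
weighted sums mean the sample expresses resistance-associated genes
highly; predicted sensitivity is the negated score.  A dose-response AUC
helper supports comparison against measured viability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ExpressionState

logger = logging.getLogger("resistscreen")


def vst_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Variance-stabilizing normalization of raw counts.

    Implemented as a shifted-log CPM: log2(1e6 * (c + 0.5) / N + 1) per
    sample, with N the sample's shifted library size.  The subsequent
    per-gene z-scoring makes downstream scores insensitive to the exact
    monotone transform; externally normalized matrices pass through with
    only the state flipped.
    """
    if expr.state != ExpressionState.raw_counts:
        return expr.with_values(expr.values, ExpressionState.normalized)
    vals = expr.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative values in raw counts")
    shifted = vals + 0.5
    libsize = shifted.sum(axis=0)
    out = np.log2(1e6 * shifted / libsize + 1.0)
    return expr.with_values(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        ExpressionState.normalized,
    )


def zscore_genes(expr: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Per-gene z-score across samples; zero-variance genes set to 0."""
    if expr.state != ExpressionState.normalized:
        raise ValueError(f"zscore_genes expects normalized input, got {expr.state.value}")
    vals = expr.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    zero = sd == 0
    if zero.any():
        logger.warning("z-score: %d constant gene(s) set to 0", int(zero.sum()))
    z = vals.sub(mean, axis=0).div(sd.where(~zero, 1.0), axis=0)
    z[zero] = 0.0
    return expr.with_values(z, ExpressionState.zscored)


def sensitivity_score(
    zscored: ExpressionMatrix,
    weights: pd.Series,
    drug: str = "",
) -> pd.DataFrame:
    """Per-sample resistance score: sum over shared genes of w_g * z_gs.

    ``predicted_sensitivity`` is the negated resistance score.  The
    gene intersection between weights and matrix is logged; an empty
    intersection is an error.
    """
    if zscored.state != ExpressionState.zscored:
        raise ValueError("sensitivity_score expects z-scored expression")
    w = weights.dropna()
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    shared = zscored.genes.intersection(w.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between weights and expression matrix")
    logger.info(
        "sensitivity score: %d/%d weighted genes found in expression matrix",
        len(shared), len(w),
    )
    z = zscored.values.loc[shared]
    score = z.mul(w.loc[shared], axis=0).sum(axis=0)
    return pd.DataFrame(
        {
            "sample_id": score.index,
            "drug": drug,
            "resistance_score": score.to_numpy(),
            "predicted_sensitivity": -score.to_numpy(),
        }
    ).reset_index(drop=True)


def classify(
    scores: pd.DataFrame,
    rule: str = "median",
    value_col: str = "predicted_sensitivity",
    thresholds: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Assign samples to groups on a score column.

    Rules: ``median`` (<= median -> 'low', else 'high'); ``tertile``
    ('sensitive' / 'intermediate' / 'resistant' by increasing resistance,
    i.e. decreasing value of ``value_col``); ``fixed`` with explicit
    ascending thresholds.  All-equal scores collapse into one group with a
    warning.
    """
    out = scores.copy()
    vals = out[value_col].to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        logger.warning("classification: all scores equal; single group")
        out["group"] = "all"
        return out
    if rule == "median":
        med = float(np.median(vals))
        out["group"] = np.where(vals <= med, "low", "high")
    elif rule == "tertile":
        q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
        # low predicted sensitivity = resistant
        out["group"] = np.select(
            [vals <= q1, vals <= q2], ["resistant", "intermediate"], default="sensitive"
        )
    elif rule == "fixed":
        if not thresholds:
            raise ValueError("rule 'fixed' requires thresholds")
        edges = [-np.inf, *sorted(thresholds), np.inf]
        labels = [f"group{i}" for i in range(1, len(edges))]
        out["group"] = pd.cut(vals, bins=edges, labels=labels).astype(str)
    else:
        raise ValueError(f"unknown classification rule '{rule}'")
    return out


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    """Viability (fraction of vehicle control) at an ordered dose series."""

    doses: np.ndarray
    viability: np.ndarray

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if len(self.doses) != len(self.viability):
            raise ValueError("doses and viability must have equal length")
        if (self.doses <= 0).any():
            raise ValueError("doses must be positive")
        if not np.all(np.diff(self.doses) > 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def auc(self) -> float:
        return dose_response_auc(self)


def dose_response_auc(dr: DoseResponse) -> float:
    """Trapezoidal area under viability vs log10(dose), normalized by the
    log-dose range so a flat viability of 1 gives AUC = 1."""
    x = np.log10(dr.doses)
    if len(x) < 2:
        raise ValueError("need at least 2 doses for an AUC")
    area = np.trapezoid(dr.viability, x)
    return float(area / (x[-1] - x[0]))
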
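"""Ranked hit tables and screen-survival integrations.

Pure reshaping of upstream result tables: per-drug top-k hit lists,
multi-drug hit rankings (competition ranking, ties by gene symbol), and
the join of screen scores with per-gene survival associations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _competition_rank(scores: pd.Series) -> pd.Series:
    """Competition ('1224') ranking, descending; deterministic under ties."""
    return scores.rank(method="min", ascending=False).astype(int)


def rank_hits(
    multidrug_scores: pd.DataFrame,
    top_k: int | None = None,
    score_col: str = "mean_l2fc_sum",
) -> pd.DataFrame:
    """Rank genes by multi-drug mean L2FC sum within each cell line x screen type.

    Descending score, competition ranking, ties broken by gene symbol in
    the row order; ``top_k`` truncates each stratum.
    """
    frames = []
    for _, sub in multidrug_scores.groupby(["cell_line", "screen_type"], sort=True):
        sub = sub.dropna(subset=[score_col]).sort_values(
            [score_col, "gene"], ascending=[False, True], kind="mergesort"
        )
        sub = sub.assign(rank=_competition_rank(sub[score_col]).to_numpy())
        if top_k is not None:
            sub = sub.head(top_k)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def rank_hits_per_drug(
    gene_scores: pd.DataFrame,
    top_k: int = 10,
) -> pd.DataFrame:
    """Top-k genes by L2FC sum for each drug in each cell line x screen type."""
    frames = []
    for _, sub in gene_scores.groupby(["cell_line", "screen_type", "drug"], sort=True):
        sub = sub.dropna(subset=["l2fc_sum"]).sort_values(
            ["l2fc_sum", "gene"], ascending=[False, True], kind="mergesort"
        )
        sub = sub.assign(rank=_competition_rank(sub["l2fc_sum"]).to_numpy())
        frames.append(sub.head(top_k))
    return pd.concat(frames, ignore_index=True)


def integrate_screen_survival(
    hit_table: pd.DataFrame,
    cox_results: pd.DataFrame,
) -> pd.DataFrame:
    """Join hit scores with per-gene survival p-values for a score-vs--log10(p)
    scatter; genes missing survival results are retained with NA and flagged."""
    cox = cox_results[["gene", "beta_hat", "hr", "p_value"]].rename(
        columns={"p_value": "survival_p"}
    )
    out = hit_table.merge(cox, on="gene", how="left")
    out["neg_log10_survival_p"] = -np.log10(out["survival_p"])
    out["missing_survival"] = out["survival_p"].isna()
    return out
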
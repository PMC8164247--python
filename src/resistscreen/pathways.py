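"""Rank-stratified gene-set enrichment over screen gene scores.

For each gene set, the replicate-minimum L2FC of the rank-1, rank-2 and
rank-3 guide per member gene is compared with the same statistic over all
other scored genes by a Wilcoxon rank-sum (Mann-Whitney) test, one-sided
toward enrichment (resistance) by default.  Sets with fewer than 10
targeted (scored) genes are excluded.  The consolidated pathway score sums
-log10 p over the three guide ranks and, when both screen modalities are
available, over knockout and activation.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger("resistscreen")

EXCLUDE_REASON_SMALL = "fewer than 10 genes targeted"


def wilcoxon_rank_sum(
    member_values: np.ndarray,
    background_values: np.ndarray,
    alternative: str = "greater",
) -> float:
    """Two-sample Wilcoxon rank-sum p-value, members vs background.

    Exact null distribution when both samples are small (m + n <= 50) and
    tie-free; otherwise the tie-corrected normal approximation with
    mid-ranks (no continuity correction).
    """
    member_values = np.asarray(member_values, dtype=float)
    background_values = np.asarray(background_values, dtype=float)
    if len(background_values) == 0:
        raise ValueError("empty background")
    m, n = len(member_values), len(background_values)
    pooled = np.concatenate([member_values, background_values])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (m + n <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        member_values, background_values, alternative=alternative,
        method=method, use_continuity=False,
    )
    return float(res.pvalue)


def pathway_wilcoxon(
    gene_values: pd.Series,
    sets: GeneSetCollection,
    alternative: str = "greater",
    min_targeted: int = 10,
) -> pd.DataFrame:
    """Per-set Wilcoxon rank-sum of member gene values vs all other scored genes.

    ``gene_values`` is one value per gene (e.g. the rank-k replicate-minimum
    L2FC); genes with NaN are not scored.  Sets whose intersection with the
    scored genes is below ``min_targeted`` are excluded with a reason.
    """
    vals = gene_values.dropna()
    scored = set(vals.index)
    rows = []
    for sid, (_, members) in sets.items():
        targeted = sorted(scored.intersection(members))
        if len(targeted) < min_targeted:
            rows.append(dict(set_id=sid, n_targeted_genes=len(targeted), p_value=np.nan,
                             excluded=True, exclusion_reason=EXCLUDE_REASON_SMALL))
            continue
        member_vals = vals.loc[targeted].to_numpy()
        bg = vals.drop(index=targeted).to_numpy()
        if len(bg) == 0:
            rows.append(dict(set_id=sid, n_targeted_genes=len(targeted), p_value=np.nan,
                             excluded=True, exclusion_reason="no background genes"))
            continue
        p = wilcoxon_rank_sum(member_vals, bg, alternative=alternative)
        rows.append(dict(set_id=sid, n_targeted_genes=len(targeted), p_value=p,
                         excluded=False, exclusion_reason=""))
    out = pd.DataFrame(rows)
    n_excl = int(out["excluded"].sum())
    if n_excl:
        logger.info("pathway test: %d/%d sets excluded (%s)", n_excl, len(out), EXCLUDE_REASON_SMALL)
    return out


def rank_stratified_pathway_test(
    gene_scores: pd.DataFrame,
    sets: GeneSetCollection,
    alternative: str = "greater",
    min_targeted: int = 10,
    use_multidrug_mean: bool = True,
    drug: str | None = None,
) -> pd.DataFrame:
    """Wilcoxon enrichment at guide ranks 1-3, per screen type.

    Gene values default to the multi-drug mean of the rank-k guide L2FC
    (matching the multi-drug resistance framing); pass ``drug`` for a
    single-drug analysis.  Returns one row per set x screen type with
    ``p_rank1..3`` and the per-screen-type partial consolidated score.
    """
    frames = []
    for st, sub in gene_scores.groupby("screen_type"):
        if drug is not None:
            sub = sub[sub["drug"] == drug]
        elif not use_multidrug_mean:
            raise ValueError("specify a drug or use the multi-drug mean")
        merged = None
        for k in (1, 2, 3):
            per_gene = sub.groupby("gene")[f"rank{k}_l2fc"].mean()
            res = pathway_wilcoxon(per_gene, sets, alternative=alternative, min_targeted=min_targeted)
            res = res.rename(columns={"p_value": f"p_rank{k}"})
            if merged is None:
                merged = res
            else:
                merged = merged.merge(res[["set_id", f"p_rank{k}"]], on="set_id", how="left")
        merged.insert(1, "screen_type", st)
        frames.append(merged)
    out = pd.concat(frames, ignore_index=True)
    pcols = [f"p_rank{k}" for k in (1, 2, 3)]
    out["score"] = -np.log10(out[pcols]).sum(axis=1, skipna=False)
    out.loc[out["excluded"], "score"] = np.nan
    out["bh_fdr_rank1"] = np.nan
    ok = out["p_rank1"].notna()
    if ok.any():
        out.loc[ok, "bh_fdr_rank1"] = multipletests(out.loc[ok, "p_rank1"], method="fdr_bh")[1]
    return out


def consolidated_score(results: pd.DataFrame) -> pd.DataFrame:
    """Sum -log10 p over guide ranks 1-3 and over available screen types.

    One row per set with ``consolidated_score`` and the number of screen
    types it covers (flagged when only one modality contributed).
    """
    scored = results[~results["excluded"]]
    agg = (
        scored.groupby("set_id", sort=True)
        .agg(
            n_targeted_genes=("n_targeted_genes", "max"),
            consolidated_score=("score", "sum"),
            n_screen_types=("screen_type", "nunique"),
        )
        .reset_index()
    )
    total_types = results["screen_type"].nunique()
    agg["partial"] = agg["n_screen_types"] < total_types
    if agg["partial"].any():
        logger.warning("consolidated score: %d set(s) missing a screen type", int(agg["partial"].sum()))
    excluded = results[results["excluded"]][["set_id", "n_targeted_genes", "exclusion_reason"]]
    excluded = excluded.drop_duplicates("set_id")
    excluded = excluded[~excluded["set_id"].isin(agg["set_id"])]
    if len(excluded):
        excluded = excluded.assign(consolidated_score=np.nan, n_screen_types=0, partial=False)
        agg = pd.concat([agg, excluded], ignore_index=True)
    return agg.sort_values("consolidated_score", ascending=False, na_position="last").reset_index(drop=True)


def fisher_combined(pvalues: np.ndarray) -> tuple[float, float]:
    """Fisher's method: statistic -2 sum ln p ~ chi2(2m) under the null."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        return np.nan, np.nan
    stat = float(-2.0 * np.log(p).sum())
    return stat, float(stats.chi2.sf(stat, df=2 * len(p)))


def pathway_survival_table(
    pathway_results: pd.DataFrame,
    cox_results: pd.DataFrame,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Join pathway enrichment with an aggregate of member-gene survival p-values.

    Per pathway: Fisher's combined chi-square over member genes' Cox
    p-values (df = 2m) plus the median member p.  Pathways with no member
    in the survival results get NA with a reason.
    """
    cox = cox_results.dropna(subset=["p_value"]).set_index("gene")["p_value"]
    rows = []
    for _, r in pathway_results.iterrows():
        sid = r["set_id"]
        members = sets.members(sid) if sid in sets.sets else []
        member_p = cox.reindex([g for g in members if g in cox.index]).dropna()
        if len(member_p) == 0:
            rows.append(dict(set_id=sid, n_members_with_survival=0,
                             fisher_stat=np.nan, fisher_p=np.nan, median_member_p=np.nan,
                             survival_note="no members with survival results"))
            continue
        stat, p = fisher_combined(member_p.to_numpy())
        rows.append(dict(set_id=sid, n_members_with_survival=len(member_p),
                         fisher_stat=stat, fisher_p=p,
                         median_member_p=float(member_p.median()), survival_note=""))
    return pathway_results.merge(pd.DataFrame(rows), on="set_id", how="left")
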
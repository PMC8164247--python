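"""Guide-level fold changes and the per-gene "L2FC sum" resistance statistic.

The scoring chain: CPM-normalize raw guide counts, exclude guides that are
unmeasurable in a given treated-vs-control comparison (count < 10 in the
untreated control and < 50 in the treated sample), take the log2 fold
change of each guide in each drug-treated sample relative to its
replicate-matched control, summarize each guide by its minimum L2FC across
replicates (a conservative, reproducibility-weighted enrichment), and
score each gene as the sum of the replicate-minimum L2FCs of its two most
enriched guides.  Positive scores indicate resistance (enrichment under
drug); the negative tail is the sensitivity side of the same table.
Multi-drug hits are the per-gene mean of the L2FC sum across the drug
panel; cross-cell-line summaries (min / mean) feed the expression-weighted
sensitivity predictor.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_formats import NONTARGETING, GuideCountMatrix, SampleSheet

logger = logging.getLogger("resistscreen")


def cpm_normalize(counts, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts-per-million per sample: 1e6 * (c + pc) / sum_col(c + pc)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mat = counts.counts if isinstance(counts, GuideCountMatrix) else counts
    shifted = mat.to_numpy(dtype=float) + pseudocount
    totals = shifted.sum(axis=0)
    if (totals == 0).any():
        bad = mat.columns[np.asarray(totals == 0).nonzero()[0][0]]
        raise ValueError(f"sample '{bad}' has all-zero counts and pseudocount 0")
    return pd.DataFrame(1e6 * shifted / totals, index=mat.index, columns=mat.columns)


def filter_guides(
    matrix: GuideCountMatrix,
    control_min: int = 10,
    treated_min: int = 50,
    logic: str = "and",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-comparison guide exclusion mask.

    A guide is excluded from a (drug, replicate) comparison when its raw
    count is below ``control_min`` in the untreated control AND below
    ``treated_min`` in the treated sample (``logic='or'`` excludes on
    either).  Returns (mask, report): mask is guides x comparisons
    (columns = treated sample ids, True = excluded); report gives the
    per-comparison exclusion fraction.
    """
    if control_min < 0 or treated_min < 0:
        raise ValueError("filter thresholds must be non-negative")
    if logic not in ("and", "or"):
        raise ValueError("logic must be 'and' or 'or'")
    comps = matrix.samples.comparisons()
    cols, rows = {}, []
    for _, c in comps.iterrows():
        low_ctrl = matrix.counts[c["control_sample"]] < control_min
        low_trt = matrix.counts[c["treated_sample"]] < treated_min
        excl = (low_ctrl & low_trt) if logic == "and" else (low_ctrl | low_trt)
        cols[c["treated_sample"]] = excl
        rows.append(
            dict(
                cell_line=c["cell_line"],
                screen_type=c["screen_type"],
                drug=c["drug"],
                replicate=c["replicate"],
                treated_sample=c["treated_sample"],
                n_excluded=int(excl.sum()),
                fraction_excluded=float(excl.mean()),
            )
        )
    mask = pd.DataFrame(cols, index=matrix.counts.index)
    report = pd.DataFrame(rows)
    logger.info(
        "guide filter (%s, control<%d & treated<%d): mean exclusion %.3f%%, retained %.3f%%",
        logic, control_min, treated_min,
        100 * report["fraction_excluded"].mean(),
        100 * (1 - report["fraction_excluded"].mean()),
    )
    return mask, report


def guide_l2fc(
    cpm: pd.DataFrame,
    samples: SampleSheet,
    library=None,
    exclude_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long table of per-replicate guide log2 fold changes.

    One row per guide per treated-vs-control comparison:
    log2(cpm_treated / cpm_control).  ``exclude_mask`` (from
    :func:`filter_guides`) marks rows excluded from downstream use.
    """
    comps = samples.comparisons()
    if comps.empty:
        raise ValueError("sample sheet contains no treated/control comparisons")
    frames = []
    gene_map = library.guide_to_gene if library is not None else None
    for _, c in comps.iterrows():
        l2fc = np.log2(cpm[c["treated_sample"]].to_numpy() / cpm[c["control_sample"]].to_numpy())
        df = pd.DataFrame(
            {
                "guide_id": cpm.index,
                "cell_line": c["cell_line"],
                "screen_type": c["screen_type"],
                "drug": c["drug"],
                "replicate": c["replicate"],
                "l2fc": l2fc,
            }
        )
        df["excluded"] = (
            exclude_mask[c["treated_sample"]].to_numpy() if exclude_mask is not None else False
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if gene_map is not None:
        out.insert(1, "gene", gene_map.reindex(out["guide_id"]).to_numpy())
    return out


def replicate_min_l2fc(guide_fc: pd.DataFrame) -> pd.DataFrame:
    """Per-guide replicate-minimum L2FC over surviving (non-excluded) replicates.

    Guides excluded in every replicate of a comparison group are flagged
    ``filtered`` and carry no score.
    """
    keys = ["guide_id", "cell_line", "screen_type", "drug"]
    if "gene" in guide_fc.columns:
        keys.insert(1, "gene")
    surviving = guide_fc[~guide_fc["excluded"]]
    agg = surviving.groupby(keys, sort=True)["l2fc"].agg(["min", "count"]).reset_index()
    agg = agg.rename(columns={"min": "replicate_min_l2fc", "count": "n_replicates"})
    all_groups = guide_fc[keys].drop_duplicates()
    out = all_groups.merge(agg, on=keys, how="left")
    out["filtered"] = out["replicate_min_l2fc"].isna()
    out["n_replicates"] = out["n_replicates"].fillna(0).astype(int)
    n_filt = int(out["filtered"].sum())
    if n_filt:
        logger.info("replicate-min: %d guide x comparison groups fully filtered", n_filt)
    return out


def gene_l2fc_sum(guide_min: pd.DataFrame, top_n: int = 2) -> pd.DataFrame:
    """Per-gene L2FC sum: the summed replicate-minimum L2FC of the top
    ``top_n`` guides (descending; ties broken by guide_id).

    Non-targeting guides are never scored.  Genes with fewer than
    ``top_n`` surviving guides get NaN and ``too_few_guides=True``.
    Rank-1..3 guide values are kept for the pathway analysis.
    """
    df = guide_min[(guide_min["gene"] != NONTARGETING) & (~guide_min["filtered"])]
    df = df.sort_values(
        ["cell_line", "screen_type", "drug", "gene", "replicate_min_l2fc", "guide_id"],
        ascending=[True, True, True, True, False, True],
        kind="mergesort",
    )
    keys = ["gene", "cell_line", "screen_type", "drug"]
    df = df.copy()
    df["_rank"] = df.groupby(keys, sort=True).cumcount() + 1
    out = df.groupby(keys, sort=True).size().rename("n_guides").reset_index()
    for k in (1, 2, 3):
        sel = (
            df.loc[df["_rank"] == k, keys + ["replicate_min_l2fc"]]
            .rename(columns={"replicate_min_l2fc": f"rank{k}_l2fc"})
        )
        out = out.merge(sel, on=keys, how="left")
    top = df[df["_rank"] <= top_n]
    sums = top.groupby(keys, sort=True)["replicate_min_l2fc"].sum().rename("l2fc_sum")
    gids = top.groupby(keys, sort=True)["guide_id"].agg(",".join).rename("contributing_guides")
    out = out.merge(sums.reset_index(), on=keys, how="left")
    out = out.merge(gids.reset_index(), on=keys, how="left")
    # genes whose guides were all filtered still get an NA row per comparison
    universe = guide_min.loc[guide_min["gene"] != NONTARGETING, keys].drop_duplicates()
    out = universe.merge(out, on=keys, how="left").sort_values(keys, kind="mergesort").reset_index(drop=True)
    out["n_guides"] = out["n_guides"].fillna(0).astype(int)
    out["too_few_guides"] = out["n_guides"] < top_n
    out.loc[out["too_few_guides"], "l2fc_sum"] = np.nan
    out.loc[out["too_few_guides"], "contributing_guides"] = ""
    n_na = int(out["too_few_guides"].sum())
    if n_na:
        logger.info("gene scoring: %d gene x comparison groups with <%d surviving guides (NA)", n_na, top_n)
    return out


def multi_drug_mean(
    gene_scores: pd.DataFrame,
    drugs: Sequence[str] | None = None,
    allow_missing_drugs: bool = False,
) -> pd.DataFrame:
    """Mean L2FC sum across the drug panel, per gene x cell line x screen type."""
    if drugs is None:
        drugs = sorted(gene_scores["drug"].unique())
    sub = gene_scores[gene_scores["drug"].isin(drugs)]
    present = sub.groupby(["gene", "cell_line", "screen_type"])["drug"].nunique()
    if (present < len(drugs)).any():
        if not allow_missing_drugs:
            missing = present[present < len(drugs)].index[0]
            raise ValueError(
                f"gene {missing[0]} ({missing[1]}, {missing[2]}) is missing drug(s) from "
                f"{sorted(drugs)}; pass allow_missing_drugs=True to average over present drugs"
            )
        logger.warning("multi-drug mean over present drugs only for some genes")
    agg = (
        sub.groupby(["gene", "cell_line", "screen_type"], sort=True)["l2fc_sum"]
        .agg(mean_l2fc_sum="mean", n_drugs="count")
        .reset_index()
    )
    return agg


def cross_cell_line(scores: pd.DataFrame, value_col: str = "mean_l2fc_sum") -> pd.DataFrame:
    """Min and mean of a per-cell-line score across cell lines, per gene x screen type.

    The min is the conservative summary used as the sensitivity-predictor
    weight; the mean is the alternative cross-line summary.
    """
    agg = (
        scores.groupby(["gene", "screen_type"], sort=True)[value_col]
        .agg(min_across_cell_lines="min", mean_across_cell_lines="mean", n_cell_lines="count")
        .reset_index()
    )
    return agg


def weight_vector(gene_scores: pd.DataFrame, drug: str, screen_type: str | None = None) -> pd.Series:
    """Per-drug predictor weights: min L2FC sum for each gene across cell lines."""
    sub = gene_scores[gene_scores["drug"] == drug]
    if screen_type is not None:
        sub = sub[sub["screen_type"] == screen_type]
    if sub.empty:
        raise ValueError(f"no gene scores for drug '{drug}'")
    w = sub.groupby("gene")["l2fc_sum"].min()
    w.name = "weight"
    return w


def combined_ko_act(cross: pd.DataFrame, value_col: str = "min_across_cell_lines") -> pd.Series:
    """Optional combined knockout + activation gene summary: sum of the two
    screen-type cross-line values (genes present in both screens only)."""
    wide = cross.pivot(index="gene", columns="screen_type", values=value_col)
    return wide.dropna().sum(axis=1).rename("combined_ko_act")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_replicate_correlation(
    guide_fc: pd.DataFrame,
    n_permutations: int = 100,
    flag_percentile: float = 75.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Spearman correlation QC of guide-level L2FCs.

    Compares (a) replicate pairs (same cell line / screen type / drug,
    different replicate), (b) non-replicate pairs (same cell line and
    screen type, different drug), (c) a scrambled null (guide labels
    permuted).  A replicate is flagged when its mean replicate-pair rho
    falls below the ``flag_percentile`` of the non-replicate distribution;
    flagged replicates are candidates for manual exclusion, mirroring the
    practice of dropping a poorly correlated replicate.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    wide = guide_fc.pivot_table(
        index="guide_id",
        columns=["cell_line", "screen_type", "drug", "replicate"],
        values="l2fc",
    ).dropna()
    cols = list(wide.columns)
    if len({c[3] for c in cols}) < 2:
        raise ValueError("replicate QC needs at least 2 replicates")
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if a[0] != b[0] or a[1] != b[1]:
                continue  # compare only within a cell line x screen type
            if a[2] == b[2] and a[3] != b[3]:
                kind = "replicate"
            elif a[2] != b[2]:
                kind = "non_replicate"
            else:
                continue
            rho = float(spearmanr(wide[a], wide[b]).statistic)
            pairs.append(dict(kind=kind, a="|".join(map(str, a)), b="|".join(map(str, b)), rho=rho))
    arr = wide.to_numpy()
    null_rhos = []
    for _ in range(n_permutations):
        i, j = rng.choice(len(cols), size=2, replace=False)
        perm = rng.permutation(arr.shape[0])
        null_rhos.append(float(spearmanr(arr[:, i], arr[perm, j]).statistic))
        pairs.append(dict(kind="scrambled", a=str(cols[i]), b=str(cols[j]), rho=null_rhos[-1]))
    pair_df = pd.DataFrame(pairs)
    nonrep = pair_df.loc[pair_df["kind"] == "non_replicate", "rho"]
    threshold = float(np.percentile(nonrep, flag_percentile)) if len(nonrep) else -np.inf
    flags = []
    for col in cols:
        mine = [
            p["rho"]
            for p in pairs
            if p["kind"] == "replicate" and ("|".join(map(str, col)) in (p["a"], p["b"]))
        ]
        if mine:
            mean_rho = float(np.mean(mine))
            flags.append(
                dict(
                    cell_line=col[0], screen_type=col[1], drug=col[2], replicate=col[3],
                    mean_replicate_rho=mean_rho, flagged=mean_rho < threshold,
                )
            )
    flag_df = pd.DataFrame(flags)
    for _, r in flag_df[flag_df["flagged"]].iterrows():
        logger.warning(
            "replicate QC flag: %s %s %s r%d mean replicate rho %.3f below threshold %.3f",
            r["cell_line"], r["screen_type"], r["drug"], r["replicate"],
            r["mean_replicate_rho"], threshold,
        )
    return {"pairs": pair_df, "flags": flag_df, "threshold": threshold}


def top_variable_guides(cpm: pd.DataFrame, n: int = 500) -> pd.DataFrame:
    """Row-z-scored CPM of the ``n`` most variable guides across samples.

    Constant rows (sd = 0) have undefined z-scores and are dropped with a
    warning before selection.
    """
    var = cpm.var(axis=1, ddof=1)
    nonconstant = var[var > 0]
    n_dropped = len(var) - len(nonconstant)
    if n_dropped:
        logger.warning("top-variable selection: %d constant guide row(s) dropped", n_dropped)
    if n > len(nonconstant):
        logger.warning("requested %d variable guides but only %d available", n, len(nonconstant))
        n = len(nonconstant)
    order = pd.DataFrame({"var": nonconstant}).sort_values(
        ["var"], ascending=False, kind="mergesort"
    )
    chosen = order.index[:n]
    sub = cpm.loc[chosen]
    return sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)


# ---------------------------------------------------------------------------
# convenience chain
# ---------------------------------------------------------------------------

def score_screen(matrix: GuideCountMatrix, config: dict | None = None) -> dict:
    """Run the full scoring chain on a count matrix; returns all tables."""
    from .io_formats import DEFAULT_CONFIG

    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    cpm = cpm_normalize(matrix, pseudocount=cfg["pseudocount"])
    mask, filter_report = filter_guides(
        matrix, control_min=cfg["control_min"], treated_min=cfg["treated_min"],
        logic=cfg["filter_logic"],
    )
    fc = guide_l2fc(cpm, matrix.samples, matrix.library, exclude_mask=mask)
    gmin = replicate_min_l2fc(fc)
    gene_scores = gene_l2fc_sum(gmin, top_n=cfg["top_n_guides"])
    multidrug = multi_drug_mean(gene_scores)
    cross = cross_cell_line(multidrug)
    return {
        "cpm": cpm,
        "filter_mask": mask,
        "filter_report": filter_report,
        "guide_l2fc": fc,
        "guide_min": gmin,
        "gene_scores": gene_scores,
        "multidrug": multidrug,
        "cross_cell_line": cross,
    }
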
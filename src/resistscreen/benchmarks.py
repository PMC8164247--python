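"""Recovery and calibration experiments over the synthetic-data generator.

These functions run the pipeline end-to-end on simulated studies with
planted truth and measure how well each stage recovers it: planted-hit
recovery by the L2FC-sum ranking, pathway test type-I error and power,
sensitivity-score recovery of the latent resistance phenotype, Cox
coefficient recovery, and the full screen -> weights -> expression ->
score -> stratified log-rank chain.  Problem sizes default to the emulated
study design (500 genes x 6 guides, 2 cell lines x 4 drugs x 3
replicates, cohorts of 185).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pancds import classify, sensitivity_score, vst_normalize, zscore_genes
from .pathways import pathway_wilcoxon, rank_stratified_pathway_test, consolidated_score
from .scoring import score_screen, weight_vector
from .survival import cox_univariate, logrank_test
from .synthetic import (
    SimConfig,
    plant_pathway,
    plant_resistance_genes,
    simulate_expression,
    simulate_gene_sets,
    simulate_screen,
    simulate_survival,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def scoring_oracle_max_diff(
    oracle_fn,
    n_instances: int = 100,
    seed: int = 0,
    max_genes: int = 120,
    n_planted: int = 3,
) -> dict:
    """Largest absolute disagreement between the scoring chain and an
    independent straight-line oracle over random screen instances.

    ``oracle_fn(counts, guide_genes, comparisons)`` must return the
    (guide replicate-min, gene L2FC-sum) maps; any structural mismatch
    (filtered / too-few-guides flags) counts as +inf.
    """
    worst = 0.0
    for s in _child_seeds(seed, n_instances):
        rng = np.random.default_rng(s)
        cfg = SimConfig(
            seed=s,
            n_genes=int(rng.integers(20, max_genes + 1)),
            cell_lines=("A", "B")[: int(rng.integers(1, 3))],
            drugs=("d1", "d2", "d3", "d4")[: int(rng.integers(1, 5))],
            replicates=int(rng.integers(2, 4)),
            n_nontargeting=10,
            library_size=float(rng.integers(5, 40)) * 1e3,
        )
        cfg = plant_resistance_genes(cfg, n_planted=n_planted, effect_log2=2.5, rng=rng)
        lib, matrix, _ = simulate_screen(cfg, rng=rng)
        res = score_screen(matrix)
        counts = {sid: matrix.counts[sid].to_dict() for sid in matrix.counts.columns}
        comps = [
            tuple(r)
            for r in matrix.samples.comparisons()[
                ["cell_line", "screen_type", "drug", "replicate", "treated_sample", "control_sample"]
            ].itertuples(index=False)
        ]
        gmin_o, gsum_o = oracle_fn(counts, lib.guide_to_gene.to_dict(), comps)
        gm = res["guide_min"].set_index(["guide_id", "cell_line", "screen_type", "drug"])
        for k, v in gmin_o.items():
            row = gm.loc[k]
            if v is None:
                worst = max(worst, 0.0 if bool(row["filtered"]) else np.inf)
            else:
                worst = max(worst, abs(float(row["replicate_min_l2fc"]) - v))
        gs = res["gene_scores"].set_index(["gene", "cell_line", "screen_type", "drug"])
        for k, v in gsum_o.items():
            row = gs.loc[k]
            if v is None:
                worst = max(worst, 0.0 if bool(row["too_few_guides"]) else np.inf)
            else:
                worst = max(worst, abs(float(row["l2fc_sum"]) - v))
    return {"value": worst, "n": n_instances}


def filter_exclusion_fraction(seed: int = 0, n_genes: int = 500) -> dict:
    """Mean per-comparison guide exclusion fraction on a default null screen."""
    cfg = SimConfig(seed=seed, n_genes=n_genes)
    _, matrix, _ = simulate_screen(cfg)
    res = score_screen(matrix)
    frac = float(res["filter_report"]["fraction_excluded"].mean())
    return {"value": frac, "n": matrix.n_guides}


def planted_hit_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    n_genes: int = 500,
    n_planted: int = 10,
    effect_log2: float = 3.0,
    n_effective_guides: int = 2,
    top_k: int = 15,
    min_recovered: int = 9,
) -> dict:
    """Fraction of seeds in which >= ``min_recovered`` of the planted genes
    rank in the top ``top_k`` by multi-drug mean L2FC sum, in every cell line."""
    successes = 0
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        cfg = SimConfig(seed=s, n_genes=n_genes)
        cfg = plant_resistance_genes(
            cfg, n_planted=n_planted, effect_log2=effect_log2,
            n_effective_guides=n_effective_guides, rng=rng,
        )
        _, matrix, truth = simulate_screen(cfg, rng=rng)
        md = score_screen(matrix)["multidrug"]
        planted = set(truth.planted_genes)
        ok = True
        for _, sub in md.groupby("cell_line"):
            top = set(sub.sort_values(["mean_l2fc_sum", "gene"], ascending=[False, True])
                      .head(top_k)["gene"])
            if len(top & planted) < min_recovered:
                ok = False
        successes += ok
    return {"value": successes / n_seeds, "n": n_seeds}


def pathway_type1_error(
    n_sets: int = 1000,
    seed: int = 0,
    n_genes: int = 500,
    alpha: float = 0.05,
    sets_per_draw: int = 50,
) -> dict:
    """Empirical type-I error of the rank-1 Wilcoxon pathway test under a
    global null (gene values iid normal, random sets)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    n_draws = int(np.ceil(n_sets / sets_per_draw))
    pvals = []
    for _ in range(n_draws):
        vals = pd.Series(rng.standard_normal(n_genes), index=genes)
        sets = simulate_gene_sets(genes, n_sets=sets_per_draw, n_undersized=0, rng=rng)
        res = pathway_wilcoxon(vals, sets)
        pvals.extend(res.loc[~res["excluded"], "p_value"].tolist())
    pvals = np.array(pvals[:n_sets])
    return {"value": float(np.mean(pvals < alpha)), "n": len(pvals), "pvalues": pvals}


def pathway_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    n_genes: int = 300,
    n_sets: int = 50,
    effect_log2: float = 1.5,
    planted_size: int = 15,
) -> dict:
    """Fraction of seeds in which the planted pathway attains the top
    consolidated score among all tested sets."""
    successes = 0
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        cfg = SimConfig(seed=s, n_genes=n_genes, drugs=("gemcitabine",), cell_lines=("PANC1",))
        genes = cfg.gene_names()
        sets = simulate_gene_sets(genes, n_sets=n_sets, n_undersized=0, rng=rng)
        members = sets.members("SET001")[:planted_size]
        cfg = plant_pathway(cfg, members, effect_log2=effect_log2, set_id="SET001")
        _, matrix, _ = simulate_screen(cfg, rng=rng)
        gs = score_screen(matrix)["gene_scores"]
        res = rank_stratified_pathway_test(gs, sets, drug="gemcitabine")
        cons = consolidated_score(res)
        successes += cons.iloc[0]["set_id"] == "SET001"
    return {"value": successes / n_seeds, "n": n_seeds}


def pancds_phenotype_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    n_genes: int = 500,
    n_weighted: int = 50,
    n_samples: int = 50,
    coupling: float = 1.0,
    rho_threshold: float = 0.8,
) -> dict:
    """Fraction of seeds with Spearman(resistance score, latent phenotype)
    >= ``rho_threshold`` when scoring with the generating weights."""
    successes = 0
    rhos = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        genes = [f"G{i:04d}" for i in range(n_genes)]
        chosen = rng.choice(n_genes, size=n_weighted, replace=False)
        weights = {genes[i]: float(rng.uniform(1.0, 6.0)) for i in chosen}
        expr, phen = simulate_expression(genes, weights, n_samples=n_samples,
                                         coupling=coupling, rng=rng)
        z = zscore_genes(vst_normalize(expr))
        sc = sensitivity_score(z, pd.Series(weights))
        sc = sc.set_index("sample_id").loc[phen.index]
        rho = float(stats.spearmanr(sc["resistance_score"], phen).statistic)
        rhos.append(rho)
        successes += rho >= rho_threshold
    return {"value": successes / n_seeds, "n": n_seeds, "rhos": np.array(rhos)}


def cox_beta_recovery(
    n_seeds: int = 100,
    seed: int = 0,
    n_samples: int = 185,
    beta: float = 1.0,
    tolerance: float = 0.25,
    censoring_rate: float = 0.2,
) -> dict:
    """Fraction of seeds with the Cox estimate within ``tolerance`` of beta."""
    successes = 0
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        phen = rng.standard_normal(n_samples)
        surv = simulate_survival(phen, beta=beta, censoring_rate=censoring_rate, rng=rng)
        fit = cox_univariate(phen, surv.table["time"].to_numpy(), surv.table["event"].to_numpy())
        successes += abs(fit["beta_hat"] - beta) <= tolerance
    return {"value": successes / n_seeds, "n": n_seeds}


def cox_null_pvalues(n_sims: int = 500, seed: int = 0, n_samples: int = 185) -> np.ndarray:
    """Cox Wald p-values for a covariate independent of exponential survival."""
    out = []
    for s in _child_seeds(seed, n_sims):
        rng = np.random.default_rng(s)
        x = rng.standard_normal(n_samples)
        surv = simulate_survival(np.zeros(n_samples), beta=0.0, censoring_rate=0.0, rng=rng)
        fit = cox_univariate(x, surv.table["time"].to_numpy(), surv.table["event"].to_numpy())
        out.append(fit["p_value"])
    return np.array(out)


def logrank_null_pvalues(n_sims: int = 500, seed: int = 0, n_samples: int = 100) -> np.ndarray:
    """Log-rank p-values for median-split groups under beta = 0."""
    out = []
    for s in _child_seeds(seed, n_sims):
        rng = np.random.default_rng(s)
        score = rng.standard_normal(n_samples)
        surv = simulate_survival(np.zeros(n_samples), beta=0.0, censoring_rate=0.0, rng=rng)
        groups = pd.Series(np.where(score <= np.median(score), "low", "high"),
                           index=surv.table["sample_id"])
        out.append(logrank_test(groups, surv)["p_value"])
    return np.array(out)


def end_to_end_survival_separation(
    n_seeds: int = 100,
    seed: int = 0,
    n_genes: int = 200,
    n_planted: int = 10,
    effect_log2: float = 3.0,
    n_samples: int = 185,
    beta: float = 1.0,
    alpha: float = 0.05,
    drug: str = "gemcitabine",
) -> dict:
    """Full chain: screen -> per-drug min-across-cell-line weights ->
    expression cohort coupled to the planted genes -> sensitivity scores ->
    median split -> log-rank.  Returns the fraction of seeds with
    p < ``alpha``."""
    successes = 0
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        cfg = SimConfig(seed=s, n_genes=n_genes, drugs=(drug,))
        cfg = plant_resistance_genes(cfg, n_planted=n_planted, effect_log2=effect_log2, rng=rng)
        _, matrix, truth = simulate_screen(cfg, rng=rng)
        gs = score_screen(matrix)["gene_scores"]
        weights = weight_vector(gs, drug=drug)
        true_w = {g: 1.0 for g in truth.planted_genes}
        expr, phen = simulate_expression(cfg.gene_names(), true_w,
                                         n_samples=n_samples, rng=rng)
        z = zscore_genes(vst_normalize(expr))
        sc = sensitivity_score(z, weights, drug=drug)
        sc = classify(sc, rule="median")
        surv = simulate_survival(phen, beta=beta, censoring_rate=0.2, rng=rng)
        groups = sc.set_index("sample_id")["group"]
        res = logrank_test(groups, surv)
        successes += res["p_value"] < alpha
    return {"value": successes / n_seeds, "n": n_seeds}
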
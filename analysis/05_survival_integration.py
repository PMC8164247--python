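"""Survival integration: per-gene Cox PH and score-stratified log-rank.

Fits a univariate Cox model per gene on the normalized expression cohort,
then tests whether the median split on predicted drug sensitivity
separates overall survival (patients predicted resistant should do
worse when the latent resistance phenotype drives the hazard).
"""

import json
from pathlib import Path

import pandas as pd

from resistscreen import io_formats, pancds, pathways, survival

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = ROOT / "survival"
    out.mkdir(parents=True, exist_ok=True)
    expr = io_formats.read_expression(ROOT / "sim" / "expression.tsv")
    norm = pancds.vst_normalize(expr)
    surv = io_formats.read_survival(ROOT / "sim" / "survival.tsv")
    truth = json.loads((ROOT / "sim" / "truth.json").read_text())

    cox = survival.cox_per_gene(norm, surv)
    cox.to_csv(out / "cox_results.tsv", sep="\t", index=False)
    planted = cox[cox["gene"].isin(truth["planted_genes"])]
    print(f"Cox fits: {int(cox['converged'].sum())}/{len(cox)} genes converged; "
          f"planted genes median HR = {planted['hr'].median():.2f}, "
          f"median p = {planted['p_value'].median():.2e}")

    scores = pd.read_csv(ROOT / "pancds" / "sensitivity_scores.tsv", sep="\t")
    groups = scores.set_index("sample_id")["group"]
    res = survival.logrank_test(groups, surv)
    pd.DataFrame([{
        "chi_square": res["chi_square"], "df": res["df"], "p_value": res["p_value"],
        **{f"events_{k}": v for k, v in res["events_per_group"].items()},
        **{f"n_{k}": v for k, v in res["n_per_group"].items()},
    }]).to_csv(out / "stratified_test.tsv", sep="\t", index=False)
    print(f"log-rank, predicted high vs low sensitivity: chi2 = {res['chi_square']:.1f}, "
          f"p = {res['p_value']:.2e}")

    sets = io_formats.read_gmt(ROOT / "sim" / "gene_sets.gmt")
    pr = pd.read_csv(ROOT / "pathway" / "pathway_results.tsv", sep="\t")
    joined = pathways.pathway_survival_table(pr, cox, sets)
    joined.to_csv(out / "pathway_survival.tsv", sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
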
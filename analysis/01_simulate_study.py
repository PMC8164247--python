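"""Simulate the full synthetic study: screen, gene sets, expression, survival.

Emulates the study design downstream stages expect — 2 PDAC-like cell
lines x 4 drugs x 3 replicates, 500 genes x 6 guides + 100 non-targeting
controls, ~5e5 reads/sample — with 10 planted multi-drug resistance genes
(log2 effect 3 in 2 guides each, forming the planted pathway), an
expression cohort of 185 samples whose planted-gene expression tracks a
latent resistance phenotype, and survival with log hazard ratio 1 on that
phenotype.  Writes all inputs plus the ground truth under results/sim/.
"""

import json
from pathlib import Path

import numpy as np

from resistscreen import io_formats, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 1


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    cfg = synthetic.SimConfig(seed=SEED, n_genes=500)
    cfg = synthetic.plant_resistance_genes(cfg, n_planted=10, effect_log2=3.0, rng=rng)
    library, matrix, truth = synthetic.simulate_screen(cfg, rng=rng)
    io_formats.write_count_table(matrix, OUT / "counts.tsv")
    io_formats.write_sample_sheet(matrix.samples, OUT / "samples.tsv")

    genes = cfg.gene_names()
    sets = synthetic.simulate_gene_sets(genes, n_sets=50, n_undersized=3,
                                        planted_members=truth.planted_genes, rng=rng)
    io_formats.write_gmt(sets, OUT / "gene_sets.gmt")

    true_weights = {g: 1.0 for g in truth.planted_genes}
    expr, phen = synthetic.simulate_expression(genes, true_weights, n_samples=185, rng=rng)
    io_formats.write_expression(expr, OUT / "expression.tsv")
    surv = synthetic.simulate_survival(phen, beta=cfg.survival_beta,
                                       censoring_rate=cfg.censoring_rate, rng=rng)
    io_formats.write_survival(surv, OUT / "survival.tsv")
    phen.to_frame().to_csv(OUT / "phenotype.tsv", sep="\t")

    (OUT / "truth.json").write_text(json.dumps({
        "seed": SEED,
        "planted_genes": truth.planted_genes,
        "planted_pathway": "PLANTED",
        "survival_beta": cfg.survival_beta,
    }, indent=2) + "\n")
    print(f"study: {matrix.n_guides} guides x {len(matrix.samples.table)} samples, "
          f"{len(sets)} gene sets, cohort n={len(surv.table)} "
          f"({int(surv.table['event'].sum())} events)")
    print(f"planted resistance genes: {', '.join(truth.planted_genes)}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
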
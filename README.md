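# resistscreen

Analysis pipeline for pooled genome-wide CRISPR knockout and activation
drug-resistance screens, built around the study design used for
pancreatic ductal adenocarcinoma (PDAC) chemotherapy screens: two cell
lines, four drugs (gemcitabine, oxaliplatin, irinotecan, 5-fluorouracil),
three replicates, ~6 sgRNAs per gene. It covers the full path from raw
guide-count tables to ranked resistance genes, enriched pathways,
expression-based drug-sensitivity prediction, and patient-survival
integration — plus a synthetic-data generator with planted ground truth so
every stage is testable end-to-end.

## Who this is for

Functional-genomics analysts who have MAGeCK-style sgRNA count tables from
a drug-resistance screen (enrichment under treatment) and want a
transparent, reproducible implementation of a simple, conservative gene
statistic and its downstream integrations, with known statistical
behaviour on simulated data.

## The statistics at its core

**Gene resistance score (the "L2FC sum").** For each guide *g* and each
drug-treated sample, compute the log2 fold change of CPM-normalized counts
against the replicate-matched untreated control,

> L2FC(g, r) = log2( CPM_treated(g, r) / CPM_control(g, r) ),

after excluding guides with < 10 counts in the control **and** < 50 in the
treated sample of that comparison. Summarize each guide by its **minimum**
L2FC across replicates — a guide only scores as high as its worst
replicate, which rewards reproducible enrichment. The gene score is the
sum of the replicate-minimum L2FCs of the gene's **top two** guides.
Positive = enrichment under drug = resistance; the negative tail is the
sensitivity side of the same table. Multi-drug hits are ranked by the mean
L2FC sum across the four drugs; cross-cell-line summaries (min / mean)
are kept for downstream weighting.

**Pathway enrichment.** For each gene set, the rank-1, rank-2 and rank-3
guide values per gene are compared with all other scored genes by a
one-sided Wilcoxon rank-sum test; sets with fewer than 10 targeted genes
are excluded. The consolidated pathway score is Σ −log10 p over the three
ranks and over the available screen modalities (knockout + activation).

**Expression-weighted sensitivity score (PancDS).** Per drug, each gene
gets a scalar weight — its minimum L2FC sum across the two cell lines.
Expression is variance-stabilized (shifted-log CPM), z-scored per gene,
and a sample's resistance score is Σ_g w_g z_gs; predicted sensitivity is
its negation. Samples are classified by median split or tertiles.

**Survival integration.** Univariate Cox proportional hazards per gene
(Newton–Raphson on the Breslow partial likelihood) against overall
survival, and a k-group log-rank test of score-stratified groups.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
simulated study (500 genes × 6 guides + 100 non-targeting controls, 10
planted resistance genes with log2 effect 3 in 2 guides, an expression
cohort of 185 samples, survival with log hazard ratio 1 on the latent
resistance phenotype):

```
python analysis/01_simulate_study.py
python analysis/02_score_screen.py
python analysis/03_pathway_enrichment.py
python analysis/04_sensitivity_scores.py
python analysis/05_survival_integration.py
python analysis/06_report_hits.py
```

Output (abridged; all tables land under `results/`):

```
study: 3100 guides x 30 samples, 54 gene sets, cohort n=185 (146 events)
guide filter excluded 0.28% of guides on average per comparison
BXPC3: 10/10 planted genes in the top 15 by multi-drug mean L2FC sum
PANC1: 10/10 planted genes in the top 15 by multi-drug mean L2FC sum
planted pathway 'PLANTED' ranks #1 with consolidated score 22.5
gemcitabine: scored 185 samples with 500 gene weights
Spearman(resistance score, latent phenotype) = 0.887
Cox fits: 500/500 genes converged; planted genes median HR = 1.50,
  median p = 3.99e-11
log-rank, predicted high vs low sensitivity: chi2 = 45.4, p = 1.62e-11
```

Reading this: the 10/50 count filter removes well under 1% of guides at
this sequencing depth; all 10 planted resistance genes top the multi-drug
ranking in both cell lines; the planted pathway wins the consolidated
score; the screen-weighted expression score tracks the latent resistance
phenotype (ρ = 0.89); and splitting the cohort on predicted sensitivity
separates survival decisively, as it should when resistance drives the
hazard.

The same stages are available as a CLI (`resistscreen simulate | score |
qc | pathway | pancds | survival | report`) and as library functions
(`resistscreen.score_screen`, `resistscreen.rank_stratified_pathway_test`,
`resistscreen.sensitivity_score`, `resistscreen.cox_per_gene`, ...).

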
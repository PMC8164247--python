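# Methods

## Scope and data model

The pipeline starts from guide-level count tables (MAGeCK-count dialect:
`sgRNA`, `gene`, one column per sample) and a sample sheet describing the
screen design (cell line, screen type knockout/activation, condition,
drug, replicate). Read-level processing (trimming, alignment, counting) is
out of scope. Gene symbols are treated as opaque, case-sensitive strings;
no identifier mapping is performed, and cross-dataset joins intersect on
exact symbol match with the intersection size logged. Every threshold
below is a config key (`resistscreen.io_formats.DEFAULT_CONFIG`, YAML
override via `load_config`).

## Gene scoring

1. **CPM normalization.** Per sample, `1e6 * (count + c) / Σ(count + c)`
   with pseudocount `c = 0.5` (default, configurable). The pseudocount
   avoids log(0) for dropout guides while leaving ranks essentially
   unchanged at screen depths.
2. **Guide filter.** A guide is excluded from a treated-vs-control
   comparison when its raw count is `< 10` in the untreated control
   **and** `< 50` in the treated sample. The conjunction ("and") is the
   default because the filter's purpose is removing guides that are
   unmeasurable on both sides — a guide at 9 control counts but 1000
   treated counts is a real enrichment signal and is kept. The disjunctive
   rule is available (`filter_logic: or`). Filtering is per comparison;
   the replicate-minimum is then taken over surviving comparisons only.
   Every filtering step logs counts removed and retained.
3. **Guide L2FC and replicate minimum.** `log2(CPM_treated / CPM_control)`
   per replicate; each guide's summary is the minimum across replicates.
   The minimum is deliberately conservative: a guide scores only as high
   as its least-enriched replicate, suppressing one-replicate artifacts.
4. **Gene L2FC sum.** Surviving guides are sorted by replicate-minimum
   L2FC (descending; ties broken lexicographically by guide id for
   determinism) and the top two are summed. Genes with fewer than two
   surviving guides are reported NA rather than scored from one guide,
   because a "top two" statistic is undefined there. Non-targeting
   controls are never scored. Rank-1/2/3 values are retained for the
   pathway analysis.
5. **Aggregation.** Multi-drug score = mean L2FC sum across the drug
   panel (missing drugs are an error unless explicitly allowed).
   Cross-cell-line summaries keep both the min (conservative; used as the
   sensitivity-predictor weight) and the mean. A combined
   knockout+activation gene summary (sum of the two screen-type values) is
   available but optional, since the consolidated combination is defined
   at the pathway level.

Positive scores mean enrichment under drug (resistance); sensitivity hits
are the negative tail of the same table.

**A note on monotonicity.** Increasing a contributing guide's treated
counts increases its gene's L2FC sum *in the regime where no single guide
is a material fraction of the library*. Because CPM renormalizes by the
sample total, inflating one guide slightly deflates all others; with
thousands of guides this effect is negligible, but in toy examples with a
handful of guides it can dominate. The test suite asserts monotonicity in
the realistic regime.

## Replicate QC

Guide-level L2FC vectors are compared by Spearman correlation between
(a) replicate pairs (same cell line, screen type and drug), (b)
non-replicate pairs (same cell line and screen type, different drug), and
(c) a scrambled null (guide labels permuted). A replicate whose mean
replicate-pair ρ falls below the 75th percentile of the non-replicate
distribution is flagged; flagged replicates are *not* dropped
automatically — exclusion is an analyst decision. A row-z-scored matrix of
the 500 most variable guides is emitted for heatmap-style inspection
(constant rows are dropped with a warning).

## Pathway enrichment

For each gene set and each guide rank k ∈ {1, 2, 3}, the rank-k
replicate-minimum L2FC of member genes is compared against all other
scored genes (default background; non-targeting controls and unscored
genes are absent by construction) with a Wilcoxon rank-sum test. Sets with
fewer than 10 *targeted* (scored) genes are excluded with a recorded
reason. Default gene values are the multi-drug mean of the rank-k value,
matching the multi-drug-resistance framing; single-drug analyses are a
flag away. Sidedness defaults to one-sided "members greater" (resistance
enrichment); a mirrored run covers sensitivity and two-sided is available.
The implementation delegates to `scipy.stats.mannwhitneyu`: exact null
when m + n ≤ 50 without ties, otherwise the mid-rank, tie-corrected normal
approximation without continuity correction. The consolidated score is
Σ −log10 p over ranks 1–3 and over available screen types (partial sums
are flagged when a modality is missing). No multiple-testing correction is
applied to the consolidated score itself — it is a ranking device — but a
Benjamini–Hochberg column on the rank-1 p-values is emitted for
interpretation. The survival join aggregates member genes' Cox p-values by
Fisher's method (−2 Σ ln p ~ χ², df = 2m) alongside the median member p;
this is reporting, not inference.

## Expression-weighted sensitivity score

Weights for drug *d* are each gene's minimum L2FC sum across the two cell
lines — the conservative cross-line summary, taken raw (no rescaling; the
score is a ranking device and any positive linear rescale is
order-preserving). Expression normalization is a shifted-log CPM,
`log2(1e6·(c + 0.5)/N + 1)`: a variance-stabilizing transform in intent,
chosen over a dispersion-model-based transform because the per-gene
z-scoring that follows makes the score insensitive to the exact monotone
transform; externally normalized matrices are accepted unchanged.
Z-scores use the sample (n−1) standard deviation (configurable);
zero-variance genes are set to 0 with a warning. The per-sample resistance
score is the total sum Σ_g w_g z_gs over the weight/matrix gene
intersection ("cumulative sum" in the sense of a single accumulated value
per sample; the intermediate trace is available for diagnostics). All
genes with finite weights contribute by default; a top-k restriction
exists. Predicted sensitivity is the negated score. Classification:
median split (ties to "low") or tertiles (resistant / intermediate /
sensitive by increasing predicted sensitivity). Dose-response AUC is the
trapezoid over viability vs log10 dose, normalized by the log-dose range
so a flat viability of 1 gives AUC 1; lower AUC = more sensitive.

## Survival

Per-gene univariate Cox proportional hazards on normalized expression:
Newton–Raphson on the Breslow partial likelihood, max 50 iterations,
gradient tolerance 1e-8, step-halving on likelihood decrease. Breslow tie
handling was chosen over Efron for its simple closed form; at the tie
rates of continuous survival simulations the difference is negligible, and
the fit is cross-checked against lifelines (Efron) on tie-free data where
the two coincide. |β| > 20 is reported as separation; zero-variance genes
and non-convergent fits are NA with a reason. Censored observations tied
with events remain in the risk set at their own time (events precede
censorings). The k-group log-rank test uses the standard
observed-minus-expected chi-square with hypergeometric variance; the
classical identity with the Cox score test at β = 0 (two groups, tie-free)
holds to 1e-6 and is asserted in tests.

## Synthetic data

The generator emulates the screen design the pipeline targets, with
defaults fixed once:

| parameter | default | rationale |
|---|---|---|
| genes × guides | 500 × 6 | desk-scale stand-in for a genome-wide library at ~6 guides/gene |
| non-targeting guides | 100 | control presence without dominating |
| design | 2 cell lines × 4 drugs × 3 replicates | the emulated screen layout |
| reads/sample (control) | 5×10⁵ | toy-scale depth giving ~160 reads/guide |
| kill factor | 0.2 | ~80% drug-induced cell death, applied as a scalar on treated means |
| NB dispersion α | 0.05 | Var = μ + αμ²; typical replicate-level overdispersion for pooled screens |
| guide-abundance log-normal σ | 0.8 | realistic representation tails, so the 10/50 filter removes a small (<1–2%) fraction |
| expression noise sd | 1.0 (log2) | biological + technical spread per gene |
| baseline expression | Uniform(3, 10) log2 | spans low- to high-expressed genes |
| survival baseline rate | ln 2 / 600 d⁻¹ | median overall survival near 600 days at phenotype 0 |
| censoring rate | 0.2 | uniform censoring, rate solved to hold in expectation |

Resistance is planted as per-guide multiplicative effects `2^effect` on
treated means (optionally restricted to drugs/cell lines); pathways are
planted by giving every member gene such an effect. The expression cohort
draws a latent resistance phenotype r ~ N(0,1) per sample and couples
weighted genes' log2 means to it (`coupling · sign(w) · r`); counts are
Poisson around the exponentiated means. Survival times are exponential
with hazard λ₀·exp(β·r). Identical seed and config give byte-identical
outputs.

**What the generator does not emulate** — and hence what passing tests do
not certify about real screens: pervasive guide-level fitness/dropout
effects (every non-planted guide is null), guide-efficiency variation,
clonal drift, batch effects, copy-number artifacts, and mapping ambiguity.
One visible consequence: in the default sparse-truth simulation,
non-replicate samples correlate more than replicates, because
different-drug samples of the same replicate share an untreated control
(correlated noise) while replicate pairs share only the few planted
signals. In real screens dense selection signal makes replicate pairs the
most correlated, and the QC test reproduces that ordering in a
dense-signal scenario with drug-specific planted effects.

Another deliberate consequence of the model: the expected L2FC sum of a
gene planted with effect 3 in 2 guides is *below* the naive 2 × 3 = 6,
because the replicate-minimum of three noisy replicates sits below their
mean; the Monte-Carlo expectation at default dispersion is ≈ 5.0 (frozen
as 4.75–5.35 in the tests). The arithmetic of the scoring rule itself is
asserted separately on noise-free inputs.

## Problem sizes in tests and the acceptance script

Recovery and calibration experiments run at the study's stated sizes
(100 seeds; 500-gene screens for hit recovery; 1000 null sets; 185-sample
cohorts for survival) and complete in a few minutes on one CPU. The
oracle-equivalence check uses 100 random screens of 20–120 genes with
varied designs and shallow depths (5k–40k reads) so that the filter and
the too-few-guides paths are genuinely exercised; the pathway-recovery
experiment uses 300-gene single-drug screens. These sizes are the
package's own choices for a thorough desk-scale study.

## Known limitations

- The Cox model is univariate only; no adjustment covariates.
- The VST is a shifted-log stand-in, not a dispersion-based transform;
  rank-based downstream steps are insensitive, absolute normalized values
  are not comparable to dispersion-model output.
- The Wilcoxon pathway test ignores inter-gene correlation within sets
  (as does the statistic it implements).
- The stratified survival test presumes the log-rank chi-square; a
  chi-square on category counts would be a different test.
- No multiple-testing correction is built into the consolidated pathway
  ranking; use the emitted BH column when interpreting individual sets.
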
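"""Synthetic screens, expression cohorts, gene sets and survival with known truth.

The generator emulates the study design the pipeline is built for: two PDAC
cell lines, four chemotherapy drugs, three replicates, ~6 guides per gene,
negative-binomial sequencing counts over a log-normally skewed guide
representation, and a global drug "kill factor" of 0.2 (~80% cell death)
that library-size normalization removes.  Resistance is planted as
per-guide log2 enrichment effects; an expression cohort couples planted
genes to a latent per-sample resistance phenotype; survival times follow a
proportional-hazards model on that phenotype.  Every output comes with a
:class:`ScreenTruth` so downstream recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    NONTARGETING,
    ExpressionMatrix,
    ExpressionState,
    GeneSetCollection,
    GuideCountMatrix,
    GuideLibrary,
    SampleSheet,
    ScreenType,
    SurvivalTable,
)

DEFAULT_CELL_LINES = ("PANC1", "BXPC3")
DEFAULT_DRUGS = ("gemcitabine", "oxaliplatin", "irinotecan", "fluorouracil")


@dataclass(frozen=True)
class PlantedGene:
    """A resistance gene planted into the screen.

    ``effect_log2`` multiplies the treated-sample mean of the first
    ``n_effective_guides`` guides of ``gene`` by ``2**effect_log2``;
    ``drugs`` / ``cell_lines`` restrict the effect (None = everywhere).
    """

    gene: str
    n_effective_guides: int
    effect_log2: float
    drugs: tuple[str, ...] | None = None
    cell_lines: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic screen.

    Defaults mirror the emulated design: 2 cell lines x 4 drugs x 3
    replicates, 6 guides/gene, expected 5e5 reads per control sample,
    NB dispersion alpha = 0.05 (Var = mu + alpha mu^2), guide-abundance
    log-normal sigma = 0.8, and a 0.2 global kill factor under drug.
    """

    seed: int = 0
    n_genes: int = 500
    guides_per_gene: int = 6
    n_nontargeting: int = 100
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    replicates: int = 3
    screen_type: ScreenType = ScreenType.knockout
    library_size: float = 5e5
    nb_dispersion: float = 0.05
    baseline_lognormal_sigma: float = 0.8
    kill_factor: float = 0.2
    planted_resistance: tuple[PlantedGene, ...] = ()
    planted_pathway: str | None = None
    survival_beta: float = 1.0
    censoring_rate: float = 0.2

    def __post_init__(self):
        if self.n_genes < 1 or self.replicates < 1 or self.guides_per_gene < 1:
            raise ValueError("degenerate design: need >=1 gene, guide and replicate")
        if self.nb_dispersion < 0 or self.baseline_lognormal_sigma <= 0:
            raise ValueError("dispersion must be >=0 and abundance sigma > 0")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        for p in self.planted_resistance:
            if not np.isfinite(p.effect_log2):
                raise ValueError(f"non-finite effect for planted gene {p.gene}")
            if p.n_effective_guides > self.guides_per_gene:
                raise ValueError(f"{p.gene}: n_effective_guides exceeds guides_per_gene")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class ScreenTruth:
    """Ground truth of a simulated study, for recovery testing."""

    config: SimConfig
    planted_guides: pd.DataFrame  # gene, guide_id, effect_log2
    planted_pathway: str | None = None
    phenotype: pd.Series | None = None  # latent per-sample resistance
    survival_beta: float | None = None

    @property
    def planted_genes(self) -> list[str]:
        return sorted(self.planted_guides["gene"].unique())


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with Var = mu + alpha mu^2 (Poisson when alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_screen(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw a full screen: (GuideLibrary, GuideCountMatrix, ScreenTruth).

    Guide abundances are log-normal and shared across samples; control
    counts are NB(library_size * abundance, alpha); treated counts use the
    same means scaled by the global kill factor, with planted (gene,
    guide) pairs further multiplied by 2**effect_log2.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    guide_rows = []
    for g in genes:
        for j in range(1, config.guides_per_gene + 1):
            guide_rows.append((f"{g}_sg{j}", g))
    for j in range(1, config.n_nontargeting + 1):
        guide_rows.append((f"NT_sg{j:04d}", NONTARGETING))
    library = GuideLibrary(
        pd.DataFrame(guide_rows, columns=["guide_id", "gene"]),
        screen_type=config.screen_type,
    )
    n_guides = len(library.table)
    abundance = rng.lognormal(mean=0.0, sigma=config.baseline_lognormal_sigma, size=n_guides)
    abundance /= abundance.sum()
    control_mean = config.library_size * abundance

    # per-guide treated multiplier per (cell line, drug)
    guide_pos = {gid: i for i, gid in enumerate(library.guide_ids)}
    planted_rows = []
    effect = {}  # (cell_line, drug) -> multiplier vector
    for cl in config.cell_lines:
        for drug in config.drugs:
            effect[(cl, drug)] = np.ones(n_guides)
    for p in config.planted_resistance:
        gids = [f"{p.gene}_sg{j}" for j in range(1, p.n_effective_guides + 1)]
        for gid in gids:
            planted_rows.append((p.gene, gid, p.effect_log2))
        for cl in p.cell_lines or config.cell_lines:
            for drug in p.drugs or config.drugs:
                for gid in gids:
                    effect[(cl, drug)][guide_pos[gid]] *= 2.0 ** p.effect_log2

    sheet_rows, count_cols = [], {}
    st = config.screen_type.value
    for cl in config.cell_lines:
        for rep in range(1, config.replicates + 1):
            sid = f"{cl}_{st}_control_r{rep}"
            sheet_rows.append((sid, cl, st, "control", "", rep))
            count_cols[sid] = _nb_draw(rng, control_mean, config.nb_dispersion)
            for drug in config.drugs:
                tid = f"{cl}_{st}_{drug}_r{rep}"
                sheet_rows.append((tid, cl, st, "treated", drug, rep))
                mu = control_mean * config.kill_factor * effect[(cl, drug)]
                count_cols[tid] = _nb_draw(rng, mu, config.nb_dispersion)

    samples = SampleSheet(
        pd.DataFrame(
            sheet_rows,
            columns=["sample_id", "cell_line", "screen_type", "condition", "drug", "replicate"],
        )
    )
    counts = pd.DataFrame(count_cols, index=library.guide_ids).astype(np.int64)
    counts.index.name = "guide_id"
    matrix = GuideCountMatrix(counts=counts, library=library, samples=samples)
    truth = ScreenTruth(
        config=config,
        planted_guides=pd.DataFrame(planted_rows, columns=["gene", "guide_id", "effect_log2"]),
        planted_pathway=config.planted_pathway,
        survival_beta=config.survival_beta,
    )
    return library, matrix, truth


def plant_resistance_genes(
    config: SimConfig,
    n_planted: int = 10,
    n_effective_guides: int = 2,
    effect_log2: float = 3.0,
    rng: np.random.Generator | None = None,
) -> SimConfig:
    """Return a config with ``n_planted`` genes planted (chosen by rng)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    chosen = rng.choice(len(genes), size=n_planted, replace=False)
    planted = tuple(
        PlantedGene(genes[i], n_effective_guides, effect_log2) for i in sorted(chosen)
    )
    return replace(config, planted_resistance=config.planted_resistance + planted)


# ---------------------------------------------------------------------------
# expression cohort
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: Sequence[str],
    weights: Mapping[str, float],
    n_samples: int,
    coupling: float = 1.0,
    noise_sd: float = 1.0,
    baseline_log2_range: tuple[float, float] = (3.0, 10.0),
    count_noise: bool = True,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "P",
):
    """Expression cohort whose weighted genes track a latent resistance phenotype.

    Each sample s draws a latent resistance r_s ~ N(0,1).  On the log2
    scale, gene g in sample s has mean b_g + coupling * r_s * sign(w_g)
    for genes with nonzero weight (plus N(0, noise_sd) noise); values are
    exponentiated to Poisson counts (or left as continuous intensities
    with ``count_noise=False``).  Returns (ExpressionMatrix raw_counts,
    phenotype Series).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    genes = list(genes)
    w = np.array([float(weights.get(g, 0.0)) for g in genes])
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    phen = rng.standard_normal(n_samples)
    baseline = rng.uniform(*baseline_log2_range, size=len(genes))
    direction = np.sign(w) * (w != 0)
    log2_mean = baseline[:, None] + coupling * direction[:, None] * phen[None, :]
    if noise_sd > 0:
        log2_mean = log2_mean + rng.normal(0.0, noise_sd, size=log2_mean.shape)
    intensity = np.exp2(log2_mean)
    values = rng.poisson(intensity).astype(float) if count_noise else intensity
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(1, n_samples + 1)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids),
        state=ExpressionState.raw_counts,
    )
    return expr, pd.Series(phen, index=sample_ids, name="phenotype")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(
    phenotype,
    beta: float,
    censoring_rate: float = 0.2,
    baseline_rate: float = np.log(2) / 600.0,
    rng: np.random.Generator | None = None,
) -> SurvivalTable:
    """Exponential survival with hazard lambda0 * exp(beta * phenotype).

    Censoring is an independent Uniform(0, u) time with u solved so that
    the expected censoring fraction equals ``censoring_rate``.  The
    default baseline rate puts median survival near 600 days for a
    phenotype of 0.
    """
    if abs(beta) >= 5:
        raise ValueError("|beta| must be < 5")
    if rng is None:
        rng = np.random.default_rng(0)
    phen = pd.Series(phenotype)
    lam = baseline_rate * np.exp(beta * phen.to_numpy(dtype=float))
    times = rng.exponential(1.0 / lam)
    event = np.ones(len(times), dtype=int)
    if censoring_rate > 0:
        # P(C < T | lambda) for C ~ U(0,u), T ~ Exp(lambda): (1 - e^{-lu})/(lu)
        def expected_censoring(u):
            x = lam * u
            return float(np.mean(np.where(x < 1e-12, 1.0, (1.0 - np.exp(-x)) / np.maximum(x, 1e-300))))

        lo, hi = 1e-9 / baseline_rate, 1e9 / baseline_rate
        u = brentq(lambda v: expected_censoring(v) - censoring_rate, lo, hi)
        cens = rng.uniform(0.0, u, size=len(times))
        event = (times <= cens).astype(int)
        times = np.minimum(times, cens)
    if isinstance(phen.index, pd.RangeIndex):
        ids = [f"P{i:04d}" for i in range(1, len(phen) + 1)]
    else:
        ids = [str(s) for s in phen.index]
    return SurvivalTable(pd.DataFrame({"sample_id": ids, "time": times, "event": event}))


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    genes: Sequence[str],
    n_sets: int = 50,
    size_range: tuple[int, int] = (10, 50),
    n_undersized: int = 3,
    planted_members: Sequence[str] | None = None,
    planted_set_id: str = "PLANTED",
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """Random gene sets of size 10-50, plus undersized sets (to exercise the
    <10-targeted-genes exclusion) and optionally one planted set."""
    if rng is None:
        rng = np.random.default_rng(0)
    genes = list(genes)
    sets: dict[str, tuple[str, list[str]]] = {}
    if planted_members is not None:
        sets[planted_set_id] = ("planted resistance pathway", list(planted_members))
    for i in range(1, n_sets + 1):
        size = min(int(rng.integers(size_range[0], size_range[1] + 1)), len(genes))
        members = [genes[j] for j in sorted(rng.choice(len(genes), size=size, replace=False))]
        sets[f"SET{i:03d}"] = (f"random set {i}", members)
    for i in range(1, n_undersized + 1):
        size = int(rng.integers(2, 10))
        members = [genes[j] for j in sorted(rng.choice(len(genes), size=size, replace=False))]
        sets[f"SMALL{i:02d}"] = (f"undersized set {i}", members)
    return GeneSetCollection(sets)


def plant_pathway(
    config: SimConfig,
    members: Sequence[str],
    effect_log2: float,
    n_effective_guides: int = 2,
    set_id: str = "PLANTED",
) -> SimConfig:
    """Plant per-gene guide effects for every member of a pathway."""
    planted = tuple(PlantedGene(g, n_effective_guides, effect_log2) for g in members)
    return replace(
        config,
        planted_resistance=config.planted_resistance + planted,
        planted_pathway=set_id,
    )


# ---------------------------------------------------------------------------
# dose response
# ---------------------------------------------------------------------------

def simulate_dose_response(
    ic50: float,
    hill: float,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Hill-curve viability relative to vehicle: 1 / (1 + (d/ic50)^hill)."""
    from .pancds import DoseResponse

    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any() or ic50 <= 0:
        raise ValueError("doses and ic50 must be positive")
    viability = 1.0 / (1.0 + (doses / ic50) ** hill)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        viability = np.clip(viability + rng.normal(0.0, noise_sd, size=len(doses)), 0.0, None)
    return DoseResponse(doses=doses, viability=viability)
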
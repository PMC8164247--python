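"""Tabular data model and on-disk formats for pooled CRISPR screen analysis.

Everything downstream of read counting lives on a handful of validated
containers: a guide library (guide -> gene map), a sample sheet describing
the screen design (cell line x screen type x drug x replicate), the raw
guide x sample count matrix, GMT gene-set collections, gene x sample
expression matrices, and survival tables.  All on-disk formats are plain
TSV (MAGeCK-count dialect for counts) or standard GMT; readers validate
eagerly and report the file, line, and field at fault.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("resistscreen")

#: Sentinel gene symbol for non-targeting control guides.
NONTARGETING = "NONTARGETING"


class ScreenType(str, Enum):
    """Perturbation modality: nuclease knockout or dCas9-SAM activation."""

    knockout = "knockout"
    activation = "activation"


class ExpressionState(str, Enum):
    raw_counts = "raw_counts"
    normalized = "normalized"
    zscored = "zscored"


class FormatError(ValueError):
    """Malformed on-disk input; message names file, line and field."""


def _fail(path, line: int | None, field_name: str, msg: str):
    loc = f"{path}" + (f", line {line}" if line is not None else "")
    raise FormatError(f"{loc}, field '{field_name}': {msg}")


# ---------------------------------------------------------------------------
# guide library
# ---------------------------------------------------------------------------

@dataclass
class GuideLibrary:
    """Guide -> gene map for one screen library.

    ``table`` has columns ``guide_id`` (unique) and ``gene``; non-targeting
    controls carry the sentinel :data:`NONTARGETING` as gene.
    """

    table: pd.DataFrame
    screen_type: ScreenType | None = None

    def __post_init__(self):
        t = self.table
        for col in ("guide_id", "gene"):
            if col not in t.columns:
                raise ValueError(f"guide library missing column '{col}'")
        dup = t["guide_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate guide_id(s): {sorted(t.loc[dup, 'guide_id'].unique()[:5])}"
            )
        multi = t.groupby("guide_id")["gene"].nunique()
        if (multi > 1).any():
            raise ValueError("a guide maps to more than one gene")
        self.table = t.reset_index(drop=True)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def guide_to_gene(self) -> pd.Series:
        return self.table.set_index("guide_id")["gene"]

    def targeting_genes(self) -> pd.Index:
        g = self.table["gene"]
        return pd.Index(sorted(g[g != NONTARGETING].unique()))


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "cell_line", "screen_type", "condition", "drug", "replicate"]


@dataclass
class SampleSheet:
    """Screen design: one row per sequenced sample.

    Columns: ``sample_id`` (unique), ``cell_line``, ``screen_type``
    (knockout/activation), ``condition`` (control/treated), ``drug``
    (empty for controls) and ``replicate`` (positive integer).  Every
    treated sample must have a matching control of the same cell line,
    screen type and replicate.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table.copy()
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"sample sheet missing column(s) {missing}")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        bad = ~t["condition"].isin(["control", "treated"])
        if bad.any():
            raise ValueError(f"condition must be control/treated, got {t.loc[bad, 'condition'].unique()}")
        bad = ~t["screen_type"].isin([s.value for s in ScreenType])
        if bad.any():
            raise ValueError(f"unknown screen_type {t.loc[bad, 'screen_type'].unique()}")
        t["drug"] = t["drug"].fillna("").astype(str)
        t["replicate"] = t["replicate"].astype(int)
        if (t["replicate"] < 1).any():
            raise ValueError("replicate numbers must be positive integers")
        controls = t[t["condition"] == "control"]
        ckeys = set(zip(controls["cell_line"], controls["screen_type"], controls["replicate"]))
        for _, row in t[t["condition"] == "treated"].iterrows():
            key = (row["cell_line"], row["screen_type"], row["replicate"])
            if key not in ckeys:
                raise ValueError(
                    f"treated sample '{row['sample_id']}' has no matching control "
                    f"for (cell_line={key[0]}, screen_type={key[1]}, replicate={key[2]})"
                )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def comparisons(self) -> pd.DataFrame:
        """One row per treated-vs-control comparison.

        Columns: cell_line, screen_type, drug, replicate, treated_sample,
        control_sample.  This is the unit at which fold changes are taken.
        """
        t = self.table
        controls = t[t["condition"] == "control"].set_index(["cell_line", "screen_type", "replicate"])
        rows = []
        for _, r in t[t["condition"] == "treated"].iterrows():
            ctrl = controls.loc[(r["cell_line"], r["screen_type"], r["replicate"])]
            if isinstance(ctrl, pd.DataFrame):
                ctrl = ctrl.iloc[0]
            rows.append(
                dict(
                    cell_line=r["cell_line"],
                    screen_type=r["screen_type"],
                    drug=r["drug"],
                    replicate=r["replicate"],
                    treated_sample=r["sample_id"],
                    control_sample=ctrl["sample_id"],
                )
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class GuideCountMatrix:
    """Raw integer guide x sample counts plus library and design metadata."""

    counts: pd.DataFrame  # index: guide_id, columns: sample_id
    library: GuideLibrary
    samples: SampleSheet

    def __post_init__(self):
        c = self.counts
        if not c.index.equals(self.library.guide_ids):
            # allow same set, different order
            if set(c.index) != set(self.library.guide_ids):
                raise ValueError("count matrix guides do not match library")
            self.counts = c = c.loc[self.library.guide_ids]
        missing = [s for s in self.samples.sample_ids if s not in c.columns]
        if missing:
            raise ValueError(f"count matrix missing sample column(s) {missing}")
        extra = [s for s in c.columns if s not in set(self.samples.sample_ids)]
        if extra:
            raise ValueError(f"count matrix column(s) {extra} absent from sample sheet")
        self.counts = c = c[list(self.samples.sample_ids)]
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def n_guides(self) -> int:
        return self.counts.shape[0]


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "drug": str})
    try:
        return SampleSheet(df)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_count_table(path, sample_sheet_path) -> GuideCountMatrix:
    """Read a MAGeCK-count-style TSV (sgRNA, gene, one column per sample).

    The guide -> gene mapping embedded in the first two columns becomes the
    :class:`GuideLibrary`; sample columns are validated against the sheet.
    """
    samples = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sgRNA", "gene"]:
        _fail(path, 1, "header", "first two columns must be 'sgRNA' and 'gene'")
    dup = df["sgRNA"].duplicated()
    if dup.any():
        _fail(path, int(dup.idxmax()) + 2, "sgRNA", f"duplicate guide_id '{df.loc[dup.idxmax(), 'sgRNA']}'")
    for sid in samples.sample_ids:
        if sid not in df.columns:
            _fail(path, 1, sid, "sample in sample sheet has no count column")
    for col in df.columns[2:]:
        if col not in set(samples.sample_ids):
            _fail(path, 1, col, "count column absent from sample sheet")
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            _fail(path, int(vals.isna().idxmax()) + 2, col, "non-numeric count")
        if not np.allclose(vals, np.round(vals)):
            _fail(path, 1, col, "non-integer count")
    screen_types = samples.table["screen_type"].unique()
    st = ScreenType(screen_types[0]) if len(screen_types) == 1 else None
    library = GuideLibrary(df[["sgRNA", "gene"]].rename(columns={"sgRNA": "guide_id"}), screen_type=st)
    counts = df.set_index("sgRNA")[list(samples.sample_ids)].astype(np.int64)
    counts.index.name = "guide_id"
    return GuideCountMatrix(counts=counts, library=library, samples=samples)


def write_count_table(mat: GuideCountMatrix, path) -> None:
    """Canonical dialect: 'sgRNA'\\t'gene' then sample columns, no quoting."""
    out = mat.counts.copy()
    out.insert(0, "gene", mat.library.guide_to_gene.reindex(out.index).to_numpy())
    out.index.name = "sgRNA"
    out.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets: set_id -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self):
        for sid, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set '{sid}' has an empty member list")

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                _fail(path, i, "members", "GMT line has fewer than 3 fields")
            sid, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if not members:
                _fail(path, i, "members", f"gene set '{sid}' has no members")
            if sid in sets:
                _fail(path, i, "set_id", f"duplicate set_id '{sid}'")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning("gene set %s: %d duplicate member(s) removed", sid, len(members) - len(deduped))
            sets[sid] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in coll.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with an explicit normalization state.

    State transitions are one-way: raw_counts -> normalized -> zscored.
    """

    values: pd.DataFrame  # index: gene symbol, columns: sample_id
    state: ExpressionState = ExpressionState.raw_counts

    def __post_init__(self):
        self.state = ExpressionState(self.state)
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")
        if self.state != ExpressionState.raw_counts and self.values.isna().any().any():
            raise ValueError("NaN values in normalized expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, state: ExpressionState) -> "ExpressionMatrix":
        order = {s: i for i, s in enumerate(ExpressionState)}
        if order[ExpressionState(state)] < order[self.state]:
            raise ValueError(f"illegal state transition {self.state.value} -> {state}")
        return ExpressionMatrix(values=values, state=state)


def read_expression(path, state: ExpressionState | str = ExpressionState.raw_counts) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        col = vals.columns[vals.isna().any().to_numpy().argmax()]
        _fail(path, None, col, "non-numeric expression value")
    return ExpressionMatrix(values=vals, state=ExpressionState(state))


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTable:
    """Per-sample overall survival: time (days, > 0) and event (1) / censor (0)."""

    table: pd.DataFrame  # columns sample_id, time, event [, treatment]

    def __post_init__(self):
        t = self.table
        for col in ("sample_id", "time", "event"):
            if col not in t.columns:
                raise ValueError(f"survival table missing column '{col}'")
        if (t["time"] <= 0).any():
            bad = t.loc[t["time"] <= 0, "sample_id"].iloc[0]
            raise ValueError(f"non-positive survival time for sample '{bad}'")
        if not t["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in survival table")
        self.table = t.reset_index(drop=True)

    def __len__(self):
        return len(self.table)


def read_survival(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    try:
        return SurvivalTable(df)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def write_survival(surv: SurvivalTable, path) -> None:
    surv.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "pseudocount": 0.5,          # added to all counts before CPM
    "control_min": 10,           # guide filter: untreated-control count threshold
    "treated_min": 50,           # guide filter: treated count threshold
    "filter_logic": "and",       # exclude when low in control AND treated ('or' available)
    "top_n_guides": 2,           # guides per gene entering the L2FC sum
    "min_pathway_genes": 10,     # pathways with fewer targeted genes are excluded
    "pathway_alternative": "greater",
    "zscore_ddof": 1,            # sample sd in gene z-scores
    "qc_flag_percentile": 75.0,  # replicate flagged below this pct of non-replicate rho
    "n_top_variable": 500,
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Merge a YAML key-value config over the documented defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg.update(user)
    return cfg
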
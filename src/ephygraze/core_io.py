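"""Domain types, tabular readers/writers, configuration and logging.

All interchange is plain UTF-8 TSV with '.' decimal separator: count
matrices are taxa × samples (cells L⁻¹), OTU tables are the classic
layout (OTU id, per-sample integer counts, trailing lineage column), and
sample design metadata lives in a sidecar TSV rather than being encoded
in sample names.

Rates and abundances are stored in the units used throughout the
analysis: cells L⁻¹, cells ind⁻¹ d⁻¹, μg C L⁻¹, nM h⁻¹.  One scale note:
microplankton biomass tables of this study family are printed on a
"×10 μg C" scale which is actually ×10⁻¹ μg C — only that reading is
consistent with abundance × per-cell carbon from the allometric
equations — and helpers here adopt the ×10⁻¹ convention explicitly in
column names (``*_x10ugC``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("ephygraze")

TAXON_GROUPS = frozenset({
    "Dinophyceae", "AloricateCiliate", "Tintinnid", "Metazoa",
    "Coccolithophyceae", "Bacillariophyceae", "Mediophyceae",
    "Fragilariophyceae", "Coscinodiscophyceae", "Dictyochophyceae",
    "Other",
})
CARBON_MODELS = frozenset({"diatom", "non_diatom", "fixed"})
TIMEPOINTS = frozenset({"T0", "T24"})
CONDITIONS = frozenset({"control", "treatment"})


class ValidationError(ValueError):
    """Raised when an input table or configuration fails validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRecord:
    """One microplankton taxon: identity, group, biovolume, carbon model.

    ``carbon_model`` selects the allometric carbon-quota equation
    (``diatom`` / ``non_diatom``) or a fixed per-cell quota in pg C
    (``fixed``, which requires ``fixed_quota``).
    """

    taxon_id: str
    name: str
    group: str
    biovolume: float            # μm³ per cell
    carbon_model: str
    fixed_quota: float | None = None   # pg C cell⁻¹, iff carbon_model == "fixed"

    def __post_init__(self) -> None:
        if self.group not in TAXON_GROUPS:
            raise ValidationError(f"unknown group {self.group!r} for taxon {self.taxon_id!r}")
        if self.carbon_model not in CARBON_MODELS:
            raise ValidationError(
                f"unknown carbon_model {self.carbon_model!r} for taxon {self.taxon_id!r}")
        if not self.biovolume > 0:
            raise ValidationError(f"biovolume must be > 0 for taxon {self.taxon_id!r}")
        if self.carbon_model == "fixed":
            if self.fixed_quota is None or not self.fixed_quota > 0:
                raise ValidationError(
                    f"carbon_model='fixed' requires fixed_quota > 0 (taxon {self.taxon_id!r})")


@dataclass(frozen=True)
class MicrocosmDesign:
    """Bottle-incubation design: volume, predator load, duration, replication."""

    volume: float = 2.2          # L per bottle
    n_predators: int = 5         # ephyrae per treatment bottle
    duration: float = 1.0        # days
    n_control_reps: int = 3
    n_treatment_reps: int = 3

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ValidationError("bottle volume must be > 0")
        if self.n_predators < 1:
            raise ValidationError("n_predators must be >= 1")
        if not self.duration > 0:
            raise ValidationError("duration must be > 0")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    timepoint: str   # "T0" | "T24"
    condition: str   # "control" | "treatment"
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"sample {self.sample_id!r}: bad timepoint {self.timepoint!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"sample {self.sample_id!r}: bad condition {self.condition!r}")
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id!r}: replicate must be >= 1")


def _check_sample_metas(samples: Sequence[SampleMeta]) -> None:
    seen: set[tuple[str, str, int]] = set()
    ids: set[str] = set()
    for s in samples:
        key = (s.timepoint, s.condition, s.replicate)
        if key in seen:
            raise ValidationError(f"duplicate sample design cell {key}")
        if s.sample_id in ids:
            raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
        seen.add(key)
        ids.add(s.sample_id)


@dataclass
class CountMatrix:
    """Cells L⁻¹ per taxon × microcosm sample, with design metadata.

    ``data`` is a DataFrame indexed by taxon_id with one column per
    sample_id, ordered as ``samples``.
    """

    data: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        _check_sample_metas(self.samples)
        ids = [s.sample_id for s in self.samples]
        missing = [c for c in self.data.columns if c not in ids]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        absent = [i for i in ids if i not in self.data.columns]
        if absent:
            raise ValidationError(f"metadata rows without sample columns: {absent}")
        self.data = self.data[ids].astype(float)
        self.data.index.name = "taxon_id"
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()])
            raise ValidationError(f"duplicate taxon ids: {dups}")
        neg = self.data < 0
        if neg.to_numpy().any():
            taxon = self.data.index[neg.any(axis=1)][0]
            sample = self.data.columns[neg.loc[taxon].to_numpy()][0]
            raise ValidationError(
                f"negative abundance for taxon {taxon!r} in sample {sample!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def meta_of(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(self, timepoint: str | None = None, condition: str | None = None) -> pd.DataFrame:
        """Columns of ``data`` restricted to a design cell."""
        cols = [s.sample_id for s in self.samples
                if (timepoint is None or s.timepoint == timepoint)
                and (condition is None or s.condition == condition)]
        return self.data[cols]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.data.copy(), list(self.samples))


@dataclass
class OtuTable:
    """Integer read counts per OTU × sample plus lineage strings.

    ``counts`` is indexed by OTU id; ``lineages`` maps OTU id to a
    rank-delimited lineage string (``domain;phylum;...``), possibly
    ``"Unclassified"``.
    """

    counts: pd.DataFrame
    lineages: pd.Series
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        _check_sample_metas(self.samples)
        ids = [s.sample_id for s in self.samples]
        absent = [i for i in ids if i not in self.counts.columns]
        if absent:
            raise ValidationError(f"metadata rows without sample columns: {absent}")
        extra = [c for c in self.counts.columns if c not in ids]
        if extra:
            raise ValidationError(f"samples without metadata: {extra}")
        if self.counts.index.has_duplicates:
            dups = sorted(self.counts.index[self.counts.index.duplicated()])
            raise ValidationError(f"duplicate OTU ids: {dups}")
        arr = self.counts[ids].to_numpy()
        if (arr < 0).any() or not (arr == arr.astype(int)).all():
            bad = self.counts.index[((self.counts[ids] < 0) |
                                     (self.counts[ids] % 1 != 0)).any(axis=1)][0]
            raise ValidationError(f"non-integer or negative count for OTU {bad!r}")
        self.counts = self.counts[ids].astype(int)
        self.counts.index.name = "otu_id"
        missing_lin = [i for i in self.counts.index if i not in self.lineages.index]
        if missing_lin:
            raise ValidationError(f"OTUs without lineage: {missing_lin}")
        self.lineages = self.lineages.reindex(self.counts.index).astype(str)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, otu_ids: Iterable[str]) -> "OtuTable":
        keep = [o for o in self.otu_ids if o in set(otu_ids)]
        return OtuTable(self.counts.loc[keep].copy(), self.lineages.loc[keep].copy(),
                        list(self.samples))

    def copy(self) -> "OtuTable":
        return OtuTable(self.counts.copy(), self.lineages.copy(), list(self.samples))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Sidecar TSV with columns sample_id, timepoint, condition, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "timepoint", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"metadata file {path} must have columns {sorted(required)}")
    return [SampleMeta(r.sample_id, r.timepoint, r.condition, int(r.replicate))
            for r in df.itertuples()]


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([{"sample_id": s.sample_id, "timepoint": s.timepoint,
                   "condition": s.condition, "replicate": s.replicate}
                  for s in samples]).to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path, meta: str | Path) -> CountMatrix:
    """Read a taxa × samples TSV (first column taxon_id) plus metadata sidecar."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    metas = read_sample_meta(meta)
    known = {s.sample_id for s in metas}
    for col in df.columns:
        if col not in known:
            raise ValidationError(f"sample {col!r} in {path} has no metadata row")
    metas = [s for s in metas if s.sample_id in df.columns]
    cm = CountMatrix(df, metas)
    logger.info("read_count_matrix: %d taxa x %d samples from %s",
                len(cm.taxa), len(cm.samples), path)
    return cm


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       float_format: str | None = None) -> None:
    cm.data.to_csv(path, sep="\t", index_label="taxon_id", float_format=float_format)


def read_otu_table(path: str | Path, meta: str | Path) -> OtuTable:
    """Classic OTU table: first column OTU id, last column lineage, middle counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty or df.columns[-1].lower() not in {"taxonomy", "lineage"}:
        raise ValidationError(
            f"{path}: last column must be the lineage (named 'taxonomy' or 'lineage')")
    lineages = df[df.columns[-1]].astype(str)
    counts = df[df.columns[:-1]]
    bad = counts.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna()
    if bad.to_numpy().any():
        otu = counts.index[bad.any(axis=1)][0]
        raise ValidationError(f"{path}: non-numeric count for OTU {otu!r}")
    metas = read_sample_meta(meta)
    metas = [s for s in metas if s.sample_id in counts.columns]
    table = OtuTable(counts, lineages, metas)
    logger.info("read_otu_table: %d OTUs x %d samples from %s",
                len(table.otu_ids), len(table.samples), path)
    return table


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    out = table.counts.copy()
    out["taxonomy"] = table.lineages
    out.to_csv(path, sep="\t", index_label="otu_id")


def read_taxon_table(path: str | Path) -> dict[str, TaxonRecord]:
    """TSV with columns taxon_id, name, group, biovolume_um3, carbon_model[, fixed_quota_pg]."""
    df = pd.read_csv(path, sep="\t")
    records: dict[str, TaxonRecord] = {}
    for r in df.itertuples():
        fixed = getattr(r, "fixed_quota_pg", None)
        if fixed is not None and pd.isna(fixed):
            fixed = None
        rec = TaxonRecord(str(r.taxon_id), str(getattr(r, "name", r.taxon_id)),
                          str(r.group), float(r.biovolume_um3), str(r.carbon_model),
                          fixed)
        if rec.taxon_id in records:
            raise ValidationError(f"duplicate taxon_id {rec.taxon_id!r} in {path}")
        records[rec.taxon_id] = rec
    return records


def load_table1_taxa() -> pd.DataFrame:
    """The bundled 28-taxon microplankton reference table (biovolumes, T0
    abundances and per-ephyra ingestion rates of the 24-h microcosm study)."""
    path = Path(__file__).parent / "data" / "table1_microplankton.tsv"
    return pd.read_csv(path, sep="\t", index_col=0)


def taxon_records_from_table1(df: pd.DataFrame | None = None) -> dict[str, TaxonRecord]:
    if df is None:
        df = load_table1_taxa()
    return {tid: TaxonRecord(tid, row["name"], row["group"],
                             float(row["biovolume_um3"]), row["carbon_model"])
            for tid, row in df.iterrows()}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """Flat run configuration; defaults are the study constants."""

    # microcosm design
    volume: float = 2.2                 # L
    n_predators: int = 5
    duration: float = 1.0               # days
    n_control_reps: int = 3
    n_treatment_reps: int = 3
    # carbon conversion constants
    het_prok_fg_c: float = 20.0         # fg C cell⁻¹, heterotrophic prokaryotes
    synechococcus_fg_c: float = 200.0   # fg C cell⁻¹
    nano_fg_c_per_um3: float = 183.0    # fg C μm⁻³, nanoplankton spheres
    # leucine assay constants
    leu_to_carbon_kg_per_mol: float = 1.55
    isotope_dilution: float = 2.0
    specific_activity_ci_per_mmol: float = 52.9
    # community statistics
    rarefaction_repeats: int = 100
    anosim_permutations: int = 999
    ra_threshold_pct: float = 1.0
    seed: int = 0

    @property
    def design(self) -> MicrocosmDesign:
        return MicrocosmDesign(self.volume, self.n_predators, self.duration,
                               self.n_control_reps, self.n_treatment_reps)


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None) -> Config:
    """Load a flat ``key: value`` / ``key=value`` config file; absent keys
    keep their defaults, unknown keys log a warning."""
    cfg = Config()
    if path is None:
        return cfg
    text = Path(path).read_text(encoding="utf-8")
    # accept key=value lines by rewriting them to YAML
    lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped and not stripped.startswith("#") and "=" in line and ":" not in line:
            key, _, val = line.partition("=")
            lines.append(f"{key.strip()}: {val.strip()}")
        else:
            lines.append(line)
    try:
        raw = yaml.safe_load("\n".join(lines))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        lineno = mark.line + 1 if mark is not None else "?"
        raise ConfigError(f"{path}: parse error at line {lineno}: {exc}") from exc
    if raw is None:
        return cfg
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected key-value pairs, got {type(raw).__name__}")
    valid = {f.name for f in fields(Config)}
    updates = {}
    for key, value in raw.items():
        if key not in valid:
            logger.warning("config %s: unknown key %r ignored", path, key)
            continue
        updates[key] = value
    try:
        cfg = replace(cfg, **{k: type(getattr(cfg, k))(v) for k, v in updates.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: bad value: {exc}") from exc
    return cfg
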
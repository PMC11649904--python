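"""Shared domain types, file I/O, configuration and reproducibility helpers.

The pipeline moves five kinds of objects between stages: per-modality
feature matrices (samples x features, missing values allowed), a phenotype
table carrying the binary label and optional neuropathy scores at two
timepoints, gene-set collections (GMT), generic result tables (TSV), and a
run configuration.  Everything on disk is plain text: TSV/CSV for matrices
and tables, GMT for sets, YAML for configuration.  Missing values are
written as ``NA`` (or an empty cell) and held internally as NaN.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("modfuse")

MODALITIES = (
    "genomic",
    "transcriptomic",
    "proteomic",
    "metabolomic",
    "methylomic",
    "inflammatory",
    "clinical",
)

MISSING_MARKERS = ("NA", "")


class ModfuseError(Exception):
    """Base class for all validation and pipeline errors."""


class ValidationError(ModfuseError):
    pass


class FormatError(ModfuseError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """A samples x features numeric table tagged with its modality.

    ``data`` is a float DataFrame indexed by sample id with feature ids as
    columns; NaN marks missing entries.  Ids must be unique on both axes and
    every observed value finite.
    """

    modality: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy(dtype=float, copy=False)
        observed = values[~np.isnan(values)]
        if observed.size and not np.all(np.isfinite(observed)):
            raise ValidationError("non-finite value in feature matrix")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.modality, self.data.loc[list(sample_ids)])

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.modality, self.data.loc[:, list(feature_ids)])


@dataclass
class PhenotypeTable:
    """Per-sample binary label plus optional MNSI scores (0-10) at baseline
    and follow-up."""

    data: pd.DataFrame  # index sample_id; columns label, mnsi_baseline, mnsi_followup

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids in phenotype table: {dups}")
        if "label" not in self.data.columns:
            raise ValidationError("phenotype table requires a 'label' column")
        lab = self.data["label"]
        if not lab.dropna().isin([0, 1]).all():
            raise ValidationError("labels must be 0 (control) or 1 (case)")
        for col in ("mnsi_baseline", "mnsi_followup"):
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if ((vals < 0) | (vals > 10)).any():
                    raise ValidationError(f"{col} scores must lie in [0, 10]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def labels(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        s = self.data["label"].astype(int)
        return s if sample_ids is None else s.loc[list(sample_ids)]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]


class GeneSetCollection(Mapping[str, GeneSet]):
    """Named, non-empty sets of feature identifiers (genes, metabolites)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in self._sets:
                raise ValidationError(f"duplicate set id {s.set_id!r}")
            if not s.members:
                raise ValidationError(f"set {s.set_id!r} is empty")
            self._sets[s.set_id] = s

    def __getitem__(self, key: str) -> GeneSet:
        return self._sets[key]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self._sets[set_id].members

    def subset(self, set_ids: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(self._sets[s] for s in set_ids)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self._sets == other._sets


@dataclass
class Config:
    """Run configuration with the study's defaults.

    Defaults follow the study design this package implements: 100
    stratified 80/20 resamples,
    stratified 5-fold inner cross-validation, set-enrichment FDR 20%,
    rank-aggregation FDR 5%, predictive-model screen at AUROC > 0.5, and a
    20 x 20 (alpha, lambda) tuning grid (400 parameter sets).
    """

    n_resamples: int = 100
    train_fraction: float = 0.8
    n_folds: int = 5
    gsea_fdr: float = 0.20
    rra_fdr: float = 0.05
    auroc_screen: float = 0.5
    grid_size: int = 20
    screen_grid_size: int = 5
    n_permutations: int = 2000
    master_seed: int = 0
    baseline_modality: str | None = "clinical"
    single_pass_modalities: tuple[str, ...] = ("proteomic",)
    # QC thresholds
    snp_missing_max: float = 0.01
    maf_min: float = 0.01
    hwe_p_min: float = 1e-10
    het_z_max: float = 3.0
    metabolite_missing_max: float = 0.70
    clinical_missing_max: float = 0.10
    mahalanobis_cutoff: float = 4.0
    knn_k: int = 10
    window_upstream: int = 2000
    window_downstream: int = 500
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    gsea_weight_exponent: float = 1.0
    pc_variance_fraction: float = 0.999
    moderated_t: bool = True
    modality_paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("train_fraction", "gsea_fdr", "rra_fdr"):
            v = getattr(self, key)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{key} must be in (0,1)")
        for key in ("n_resamples", "n_folds", "grid_size", "screen_grid_size",
                    "n_permutations"):
            v = getattr(self, key)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValidationError(f"{key} must be a positive integer")


def load_config(path: str | Path) -> Config:
    """Load a YAML key/value configuration, applying defaults for absent keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path}: expected key/value mappings")
    known = {f.name for f in dc_fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"config {path}: unknown keys {sorted(unknown)}")
    if "single_pass_modalities" in raw:
        raw["single_pass_modalities"] = tuple(raw["single_pass_modalities"])
    return Config(**raw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_feature_matrix(path: str | Path, modality: str) -> FeatureMatrix:
    """Read a TSV/CSV matrix: first row feature ids, first column sample ids.

    ``NA`` or an empty cell marks a missing value.  Duplicate ids, ragged
    rows and non-numeric cells are rejected with informative errors.
    """
    path = Path(path)
    sep = _sep_for(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    width = len(lines[0].split(sep))
    for i, line in enumerate(lines[1:], start=2):
        n = len(line.split(sep))
        if n != width:
            raise FormatError(f"{path}: ragged row at line {i} ({n} fields, expected {width})")
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str,
        na_values=list(MISSING_MARKERS), keep_default_na=False,
    )
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique().tolist())
        raise FormatError(f"{path}: duplicate feature ids {dups}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    return FeatureMatrix(modality, values)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep_for(path), na_rep="NA")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member TAB member...``.

    Duplicate members within a line are de-duplicated; lines with fewer than
    three fields are rejected with their line number.
    """
    sets = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {i}: fewer than 3 fields")
        sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:])))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection):
            s = collection[set_id]
            fh.write("\t".join([s.set_id, s.description, *sorted(s.members)]) + "\n")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV; missing rendered as ``NA``."""
    if pd.Index(table.columns).has_duplicates:
        raise ValidationError("duplicate column names in result table")
    table.to_csv(path, sep="\t", na_rep="NA", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=list(MISSING_MARKERS),
                       keep_default_na=False)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = read_table(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: requires a 'sample_id' column")
    return PhenotypeTable(df.set_index("sample_id"))


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    write_table(table.data.reset_index(names="sample_id"), path)


# ---------------------------------------------------------------------------
# Reproducibility: seed derivation and sample-usage audit
# ---------------------------------------------------------------------------


def derive_seed(master_seed: int, *tokens) -> int:
    """Deterministically derive a sub-seed (< 2^31) from the master seed,
    a stage name and any further tokens (e.g. a resample index)."""
    key = ":".join([str(master_seed), *map(str, tokens)])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


class UsageLog:
    """Sample-usage audit trail for leakage checks.

    Model-fitting and tuning code records the sample ids it consumes under
    the purposes ``fit`` / ``tune``; performance evaluation records under
    ``evaluate``.  ``violations`` returns every record in which a held-out
    sample id was consumed for anything but evaluation.
    """

    def __init__(self) -> None:
        self.records: list[tuple[str, str, frozenset]] = []

    def record(self, stage: str, purpose: str, sample_ids: Iterable) -> None:
        self.records.append((stage, purpose, frozenset(sample_ids)))

    def violations(self, held_out_ids: Iterable, stage_prefix: str = "") -> list:
        held = frozenset(held_out_ids)
        out = []
        for stage, purpose, ids in self.records:
            if not stage.startswith(stage_prefix):
                continue
            if purpose != "evaluate" and ids & held:
                out.append((stage, purpose, sorted(ids & held)))
        return out


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
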
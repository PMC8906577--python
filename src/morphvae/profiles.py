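"""Profile tables: IO, validation, normalization, feature selection and splits.

A :class:`ProfileTable` holds a samples-by-features matrix of perturbation
profiles (Cell Painting morphology readouts or L1000 landmark gene
expression) together with per-sample metadata: the compound, its dose, the
plate the well sat on, and the compound's mechanism-of-action (MOA)
annotation.  Polypharmacology compounds carry two MOA labels, written in the
source tables as ``"A ∩ B"``; DMSO vehicle wells carry none and act as the
negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MOA_SEPARATOR = " ∩ "  # " ∩ "
MOA_SEPARATOR_ASCII = "|"

#: Metadata columns stored alongside the feature block.
META_COLUMNS = ("compound_id", "dose", "plate", "well", "moa", "is_dmso")

CELL_PAINTING_COMPARTMENTS = ("Cells", "Cytoplasm", "Nuclei")
CELL_PAINTING_CHANNELS = ("DNA", "RNA", "ER", "AGP", "Mito")


class SchemaError(ValueError):
    """A required metadata column is missing or malformed."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """Maps a raw feature name to its (compartment, channel) group.

    CellProfiler names features ``<Compartment>_<Measurement>_..._<Stain>...``;
    the compartment is the first underscore-delimited token and the channel is
    the first fluorescent-stain token found anywhere in the name.  Names with
    no stain token are size/shape measurements and fall into ``AreaShape``.
    L1000 genes all map to the single pseudo-group ``gene``.
    """

    raw_name: str
    compartment: str
    channel: str

    @property
    def group(self) -> str:
        if self.channel == "gene":
            return "gene"
        if self.channel == "AreaShape":
            return f"{self.compartment}-AreaShape"
        return f"{self.compartment}-{self.channel}"


def parse_feature_name(name: str, level: str = "level5") -> FeatureDescriptor:
    """Classify a feature name into its compartment/channel group."""
    if level == "l1000":
        return FeatureDescriptor(name, "gene", "gene")
    compartment = name.split("_", 1)[0]
    if compartment not in CELL_PAINTING_COMPARTMENTS:
        compartment = CELL_PAINTING_COMPARTMENTS[0]
    tokens = name.split("_")
    for channel in CELL_PAINTING_CHANNELS:
        if channel in tokens:
            return FeatureDescriptor(name, compartment, channel)
    return FeatureDescriptor(name, compartment, "AreaShape")


@dataclass
class ProfileTable:
    """Samples-by-features profile matrix with per-sample metadata.

    Parameters
    ----------
    features
        Real-valued matrix of shape ``(n_samples, n_features)``.
    feature_names
        Unique names, one per feature column.
    meta
        DataFrame with columns :data:`META_COLUMNS`; ``moa`` holds a tuple of
        MOA label strings (empty for DMSO), ``is_dmso`` is boolean.
    level
        ``"level4"`` (replicate profiles), ``"level5"`` (consensus
        signatures) or ``"l1000"``.
    """

    features: np.ndarray
    feature_names: list[str]
    meta: pd.DataFrame
    level: str = "level4"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.feature_names = list(self.feature_names)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.features.ndim != 2:
            raise SchemaError("features must be a 2-D matrix")
        n, f = self.features.shape
        if len(self.feature_names) != f:
            raise SchemaError(
                f"{len(self.feature_names)} feature names for {f} columns"
            )
        if len(set(self.feature_names)) != f:
            raise SchemaError("feature names are not unique")
        if len(self.meta) != n:
            raise SchemaError(f"{len(self.meta)} metadata rows for {n} samples")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SchemaError(f"metadata missing columns: {missing}")
        if self.level not in {"level4", "level5", "l1000"}:
            raise SchemaError(f"unknown level tag {self.level!r}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, index: np.ndarray | Sequence[int]) -> "ProfileTable":
        """Return a new table restricted to the given row indices (or mask)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ProfileTable(
            self.features[index],
            self.feature_names,
            self.meta.iloc[index].reset_index(drop=True),
            self.level,
        )

    def descriptors(self) -> list[FeatureDescriptor]:
        return [parse_feature_name(n, self.level) for n in self.feature_names]

    def to_dataframe(self, moa_separator: str = MOA_SEPARATOR) -> pd.DataFrame:
        """Flatten metadata + features into one DataFrame (for CSV/parquet)."""
        meta = self.meta.copy()
        meta["moa"] = [moa_separator.join(m) for m in meta["moa"]]
        feats = pd.DataFrame(self.features, columns=self.feature_names)
        return pd.concat([meta.reset_index(drop=True), feats], axis=1)

    def write(self, path: str | Path, dialect: str | None = None) -> None:
        path = Path(path)
        dialect = dialect or ("parquet" if path.suffix == ".parquet" else "csv")
        df = self.to_dataframe()
        df.attrs["level"] = self.level
        if dialect == "parquet":
            df.to_parquet(path, index=False)
        else:
            df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# Reading


def _parse_moa(value: object, separators: Sequence[str]) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    text = str(value).strip()
    if not text or text.lower() in {"nan", "none"}:
        return ()
    for sep in separators:
        if sep in text:
            return tuple(p.strip() for p in text.split(sep) if p.strip())
    return (text,)


def read_profiles(
    path: str | Path,
    dialect: str = "csv",
    level: str = "level4",
    column_map: Mapping[str, str] | None = None,
    moa_separator: str = MOA_SEPARATOR,
    dmso_label: str = "DMSO",
) -> ProfileTable:
    """Read a profile table from CSV or parquet.

    ``column_map`` maps the canonical metadata names (``compound_id``,
    ``dose``, ``plate``, optionally ``well`` and ``moa``) to the column names
    used in the file; unmapped canonical names are looked up verbatim.  All
    remaining columns form the feature block and must be numeric.  MOA
    strings of the form ``"A ∩ B"`` are split into a two-element tuple
    (``"|"`` accepted as an ASCII fallback separator); rows whose compound is
    ``dmso_label`` are flagged as negative controls.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "parquet":
        df = pd.read_parquet(path)
    elif dialect == "csv":
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    for canonical in ("compound_id", "dose", "plate", "well", "moa"):
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            resolved[canonical] = source
        elif canonical in ("well",):  # optional
            continue
        elif canonical == "moa":
            continue  # allowed to be absent (all unannotated)
        else:
            raise SchemaError(f"missing metadata column {source!r} for {canonical!r}")

    meta = pd.DataFrame(index=df.index)
    meta["compound_id"] = df[resolved["compound_id"]].astype(str)
    meta["dose"] = pd.to_numeric(df[resolved["dose"]], errors="coerce")
    meta["plate"] = df[resolved["plate"]].astype(str)
    meta["well"] = df[resolved["well"]].astype(str) if "well" in resolved else ""
    separators = (moa_separator, MOA_SEPARATOR_ASCII)
    if "moa" in resolved:
        meta["moa"] = [_parse_moa(v, separators) for v in df[resolved["moa"]]]
    else:
        meta["moa"] = [()] * len(df)
    dmso_col = column_map.get("is_dmso", "is_dmso")
    if dmso_col in df.columns:
        resolved["is_dmso"] = dmso_col
        meta["is_dmso"] = df[dmso_col].astype(bool)
    else:
        meta["is_dmso"] = meta["compound_id"].str.upper() == dmso_label.upper()

    feature_cols = [c for c in df.columns if c not in set(resolved.values())]
    block = df[feature_cols]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & block.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric feature value at row {r}, column {feature_cols[c]!r}"
        )
    return ProfileTable(numeric.to_numpy(float), feature_cols, meta.reset_index(drop=True), level)


# ----------------------------------------------------------------------
# Normalization


@dataclass
class MinMaxRecord:
    """Per-feature (min, max) used by the 0-1 normalization, for inversion."""

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    identity: bool = False  # L1000 passes through unchanged


def normalize_zero_one(
    table: ProfileTable, record: MinMaxRecord | None = None
) -> tuple[ProfileTable, MinMaxRecord]:
    """Map every feature column onto [0, 1] via (x - min) / (max - min).

    L1000 tables pass through unchanged (their upstream processing already
    standardizes them); the returned record is then an identity marker.
    When ``record`` is given, its stored extremes are applied instead of the
    data-derived ones (needed to place validation/test data on the training
    scale, and to keep synthetic-data tests affine-exact).
    """
    if table.level == "l1000" and record is None:
        rec = MinMaxRecord(list(table.feature_names), np.zeros(table.n_features),
                           np.ones(table.n_features), identity=True)
        return table, rec
    if record is not None:
        if record.identity:
            return table, record
        mins, maxs = record.mins, record.maxs
    else:
        mins = table.features.min(axis=0)
        maxs = table.features.max(axis=0)
        span = maxs - mins
        if np.any(span <= 0):
            bad = [table.feature_names[i] for i in np.flatnonzero(span <= 0)]
            raise ValueError(f"constant feature(s) cannot be 0-1 normalized: {bad}")
        record = MinMaxRecord(list(table.feature_names), mins, maxs)
    scaled = (table.features - mins) / (maxs - mins)
    out = replace(table, features=scaled, meta=table.meta.copy())
    return out, record


def denormalize(table: ProfileTable, record: MinMaxRecord) -> ProfileTable:
    """Invert :func:`normalize_zero_one` using its recorded extremes."""
    if record.identity:
        return table
    raw = table.features * (record.maxs - record.mins) + record.mins
    return replace(table, features=raw, meta=table.meta.copy())


# ----------------------------------------------------------------------
# Feature selection


def select_features(
    table: ProfileTable,
    blocklist: Iterable[str] = (),
    variance_threshold: float = 1e-8,
    outlier_sd: float = 15.0,
) -> tuple[ProfileTable, dict[str, str]]:
    """Drop unusable features, returning the pruned table and a reason map.

    Rules are applied in order: any missing value; blocklisted name; variance
    below ``variance_threshold``; any value more than ``outlier_sd``
    population standard deviations from the feature mean.  The report maps
    each removed feature name to the first rule that triggered.
    """
    X = table.features
    report: dict[str, str] = {}
    blockset = set(blocklist)
    keep: list[int] = []
    for i, name in enumerate(table.feature_names):
        col = X[:, i]
        if np.isnan(col).any():
            report[name] = "missing values"
            continue
        if name in blockset:
            report[name] = "blocklist"
            continue
        var = col.var()  # population variance, ddof=0
        if var < variance_threshold:
            report[name] = "low variance"
            continue
        sd = np.sqrt(var)
        if np.any(np.abs(col - col.mean()) > outlier_sd * sd):
            report[name] = "extreme outlier"
            continue
        keep.append(i)
    if not keep:
        raise ValueError("feature selection removed every feature")
    pruned = ProfileTable(
        X[:, keep],
        [table.feature_names[i] for i in keep],
        table.meta.copy(),
        table.level,
    )
    return pruned, report


def read_blocklist(path: str | Path) -> list[str]:
    """Plain-text blocklist: one feature name per line, '#' comments allowed."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


# ----------------------------------------------------------------------
# Splits


@dataclass
class SplitAssignment:
    """Train/validation/test labels per sample, stratified and seeded."""

    labels: np.ndarray  # array of {"train","validation","test"} strings
    strat_key: str
    seed: int

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.labels == split)

    def to_manifest(self) -> dict[str, object]:
        return {
            "strat_key": self.strat_key,
            "seed": self.seed,
            "labels": self.labels.tolist(),
        }


def split_stratified(
    table: ProfileTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    strat_column: str = "plate",
) -> SplitAssignment:
    """Assign 80/10/10 train/validation/test splits within each stratum.

    Strata are the unique values of ``strat_column`` (plate for Cell
    Painting, cell line for L1000).  Strata with fewer than 3 samples go
    wholly to train.  Deterministic for a given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    labels = np.empty(table.n_samples, dtype=object)
    strata = table.meta[strat_column].astype(str)
    for stratum in sorted(strata.unique()):
        idx = np.flatnonzero((strata == stratum).to_numpy())
        if len(idx) < 3:
            labels[idx] = "train"
            continue
        n = len(idx)
        n_val = int(round(fractions[1] * n))
        n_test = int(round(fractions[2] * n))
        n_val, n_test = max(n_val, 1), max(n_test, 1)
        perm = rng.permutation(idx)
        labels[perm[:n_val]] = "validation"
        labels[perm[n_val : n_val + n_test]] = "test"
        labels[perm[n_val + n_test :]] = "train"
    return SplitAssignment(labels.astype(str), strat_column, seed)


# ----------------------------------------------------------------------
# Shuffling and consensus collapse


def shuffle_columns(table: ProfileTable, seed: int = 0) -> ProfileTable:
    """Independently permute the rows of each feature column.

    This destroys all between-feature correlation while preserving every
    per-feature marginal distribution; training on the result is the
    negative control for whether a model learned correlation structure.
    """
    rng = np.random.default_rng(seed)
    shuffled = table.features.copy()
    for j in range(table.n_features):
        shuffled[:, j] = shuffled[rng.permutation(table.n_samples), j]
    return replace(table, features=shuffled, meta=table.meta.copy())


def collapse_consensus(table: ProfileTable) -> ProfileTable:
    """Collapse level-4 replicate profiles into level-5 consensus signatures.

    One output row per (compound, dose): the per-feature mean over replicate
    rows.  MOA annotations must agree across the replicates being collapsed.
    """
    if table.level != "level4":
        raise ValueError(f"expected a level4 table, got {table.level!r}")
    meta = table.meta
    key = list(zip(meta["compound_id"], meta["dose"]))
    order: dict[tuple, list[int]] = {}
    for i, k in enumerate(key):
        order.setdefault(k, []).append(i)
    rows, recs = [], []
    for (compound, dose), idx in order.items():
        moas = {tuple(meta["moa"].iloc[i]) for i in idx}
        if len(moas) > 1:
            raise ValueError(
                f"conflicting MOA annotations for compound {compound!r}: {sorted(moas)}"
            )
        rows.append(table.features[idx].mean(axis=0))
        recs.append(
            {
                "compound_id": compound,
                "dose": dose,
                "plate": "consensus",
                "well": "",
                "moa": next(iter(moas)),
                "is_dmso": bool(meta["is_dmso"].iloc[idx[0]]),
            }
        )
    return ProfileTable(
        np.asarray(rows), table.feature_names, pd.DataFrame(recs), "level5"
    )
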
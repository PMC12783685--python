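"""Profile/count table schema, I/O and well-level aggregation.

The pipeline's universal currency is a *profile table*: one row per imaged
instance (tile, field of view, or well after aggregation) carrying nine
reserved ``Metadata_`` columns plus ``D`` numeric feature columns.  Feature
columns are, by convention, every non-``Metadata_`` column; the convention
follows image-based-profiling practice (pycytominer-style dataframes).

A parallel *count table* carries a per-FOV live nuclei count (and optionally a
confluency fraction) instead of features.

Wells are addressed "A01".."P24" (row letter + zero-padded column).  Doses are
stored in uM, timepoints in hours.  DMSO rows are the negative controls: they
carry ``Metadata_role == "negative_control"`` and a null dose.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "METADATA_COLUMNS",
    "DMSO",
    "ROLE_TREATMENT",
    "ROLE_NEGATIVE_CONTROL",
    "SchemaError",
    "ValidationError",
    "IntegrityError",
    "WellCoordinate",
    "TreatmentKey",
    "ProfileTable",
    "CountTable",
    "parse_well_id",
    "make_well_id",
    "read_profiles",
    "write_profiles",
    "read_counts",
    "write_counts",
    "aggregate_to_well",
]

#: Reserved metadata columns, in canonical order.
METADATA_COLUMNS = (
    "Metadata_plate",
    "Metadata_replica",
    "Metadata_well",
    "Metadata_fov",
    "Metadata_timepoint_h",
    "Metadata_compound",
    "Metadata_dose_uM",
    "Metadata_moa",
    "Metadata_role",
)

DMSO = "DMSO"
ROLE_TREATMENT = "treatment"
ROLE_NEGATIVE_CONTROL = "negative_control"

_WELL_RE = re.compile(r"^([A-P])(\d{2})$")


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """Table content violates an invariant (NaN feature, duplicate key...)."""


class IntegrityError(ValueError):
    """Conflicting metadata within a group that must be homogeneous."""


def parse_well_id(well_id: str) -> tuple[int, int]:
    """Parse "A01" into (row, column), both 1-based.

    Raises :class:`ValidationError` for anything outside A01..P24.
    """
    m = _WELL_RE.match(str(well_id))
    if not m:
        raise ValidationError(f"malformed well id {well_id!r} (expected e.g. 'A01')")
    row = ord(m.group(1)) - ord("A") + 1
    col = int(m.group(2))
    if not 1 <= col <= 24:
        raise ValidationError(f"well column out of range in {well_id!r}")
    return row, col


def make_well_id(row: int, col: int) -> str:
    if not (1 <= row <= 16 and 1 <= col <= 24):
        raise ValidationError(f"well position ({row}, {col}) outside a 384-well grid")
    return f"{chr(ord('A') + row - 1)}{col:02d}"


@dataclass(frozen=True)
class WellCoordinate:
    """Location of one measurement: plate, experimental replica, well, FOV.

    ``fov_id`` is ``None`` only for well-aggregated records.
    """

    plate_id: str
    replica_id: str
    well_id: str
    fov_id: int | None = None

    def __post_init__(self):
        parse_well_id(self.well_id)
        if self.fov_id is not None and int(self.fov_id) < 1:
            raise ValidationError(f"fov_id must be >= 1, got {self.fov_id}")


@dataclass(frozen=True)
class TreatmentKey:
    """One evaluation condition: compound at a dose and timepoint.

    ``compound_id == "DMSO"`` is reserved for the vehicle negative control and
    is the only compound allowed (and required) to have a null dose.
    """

    compound_id: str
    dose_uM: float | None
    timepoint_h: float
    moa_label: str | None = None

    def __post_init__(self):
        is_dmso = self.compound_id == DMSO
        has_dose = self.dose_uM is not None and not (
            isinstance(self.dose_uM, float) and np.isnan(self.dose_uM)
        )
        if is_dmso and has_dose:
            raise ValidationError("DMSO must not carry a dose")
        if not is_dmso and not has_dose:
            raise ValidationError(f"compound {self.compound_id!r} requires a dose")
        if has_dose and float(self.dose_uM) <= 0:
            raise ValidationError(f"dose must be positive, got {self.dose_uM}")

    @property
    def role(self) -> str:
        return ROLE_NEGATIVE_CONTROL if self.compound_id == DMSO else ROLE_TREATMENT


def _feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if not c.startswith("Metadata_")]


@dataclass
class ProfileTable:
    """Feature profiles with plate/replica/well/FOV/treatment metadata.

    Attributes
    ----------
    data:
        DataFrame with the nine reserved metadata columns followed by the
        feature columns, one row per record.
    feature_names:
        The feature columns, order preserved from the source.
    granularity:
        "tile", "fov" or "well".
    """

    data: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)
    granularity: str = "fov"

    def __post_init__(self):
        if not self.feature_names:
            self.feature_names = _feature_columns(self.data)
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def features(self) -> np.ndarray:
        """(n_records, D) float matrix of the feature block."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def __len__(self) -> int:
        return len(self.data)

    def with_features(self, X: np.ndarray) -> "ProfileTable":
        """Same metadata, new feature block (shape must match)."""
        if X.shape != (len(self.data), self.n_features):
            raise ValidationError(
                f"feature block shape {X.shape} does not match table "
                f"({len(self.data)}, {self.n_features})"
            )
        out = self.data.copy()
        out[self.feature_names] = X
        return ProfileTable(out, list(self.feature_names), self.granularity)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required metadata column {col!r}")
        if not self.feature_names:
            raise SchemaError("profile table has no feature columns")
        if self.granularity not in ("tile", "fov", "well"):
            raise ValidationError(f"unknown granularity {self.granularity!r}")
        if len(df) == 0:  # header-only table: nothing further to check
            return
        X = df[self.feature_names]
        non_numeric = [c for c in self.feature_names if not pd.api.types.is_numeric_dtype(X[c])]
        if non_numeric:
            bad = non_numeric[0]
            idx = X[bad].apply(lambda v: not isinstance(v, (int, float, np.number))).idxmax()
            raise ValidationError(
                f"non-numeric feature value in column {bad!r} at row index {idx}"
            )
        arr = X.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite feature value at row {df.index[r]}, column "
                f"{self.feature_names[c]!r}"
            )
        # role/dose consistency
        is_dmso = df["Metadata_compound"].astype(str) == DMSO
        role = df["Metadata_role"].astype(str)
        if (is_dmso & (role != ROLE_NEGATIVE_CONTROL)).any():
            raise ValidationError("DMSO rows must have Metadata_role='negative_control'")
        if ((~is_dmso) & (role != ROLE_TREATMENT)).any():
            raise ValidationError("non-DMSO rows must have Metadata_role='treatment'")
        dose = pd.to_numeric(df["Metadata_dose_uM"], errors="coerce")
        if dose[is_dmso].notna().any():
            raise ValidationError("DMSO rows must have a null Metadata_dose_uM")
        if dose[~is_dmso].isna().any():
            raise ValidationError("treatment rows must carry a numeric dose")
        if self.granularity in ("fov", "tile"):
            key_cols = [
                "Metadata_plate",
                "Metadata_replica",
                "Metadata_well",
                "Metadata_fov",
                "Metadata_timepoint_h",
            ]
            if self.granularity == "fov" and df.duplicated(key_cols).any():
                raise ValidationError(
                    "duplicate (plate, replica, well, fov, timepoint) key at fov granularity"
                )


@dataclass
class CountTable:
    """Per-FOV live nuclei counts (and optional confluency) with metadata."""

    data: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required metadata column {col!r}")
        if "nuclei_count" not in df.columns:
            raise SchemaError("missing required column 'nuclei_count'")
        counts = pd.to_numeric(df["nuclei_count"], errors="coerce")
        if counts.isna().any() or (counts < 0).any():
            raise ValidationError("nuclei_count must be non-negative and numeric")
        if "confluency" in df.columns:
            conf = pd.to_numeric(df["confluency"], errors="coerce")
            if ((conf < 0) | (conf > 1)).any():
                raise ValidationError("confluency must lie in [0, 1]")
        key_cols = [
            "Metadata_plate",
            "Metadata_replica",
            "Metadata_well",
            "Metadata_fov",
            "Metadata_timepoint_h",
        ]
        if df.duplicated(key_cols).any():
            raise ValidationError("duplicate (plate, replica, well, fov, timepoint) count record")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "parquet"):
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    return "parquet" if suffix in (".parquet", ".pq") else "csv"


def _read_frame(path: str | Path, fmt: str | None) -> pd.DataFrame:
    fmt = _infer_format(path, fmt)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _write_frame(df: pd.DataFrame, path: str | Path, fmt: str | None) -> None:
    fmt = _infer_format(path, fmt)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_profiles(
    path: str | Path, format: str | None = None, granularity: str | None = None
) -> ProfileTable:
    """Read a profile table from CSV or Parquet.

    Granularity is inferred from ``Metadata_fov`` (all-null means
    well-aggregated) unless given explicitly.
    """
    df = _read_frame(path, format)
    if granularity is None:
        if "Metadata_fov" in df.columns and df["Metadata_fov"].isna().all():
            granularity = "well"
        else:
            granularity = "fov"
    return ProfileTable(df, granularity=granularity)


def write_profiles(table: ProfileTable, path: str | Path, format: str | None = None) -> None:
    _write_frame(table.data, path, format)


def read_counts(path: str | Path, format: str | None = None) -> CountTable:
    return CountTable(_read_frame(path, format))


def write_counts(table: CountTable, path: str | Path, format: str | None = None) -> None:
    _write_frame(table.data, path, format)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

_WELL_GROUP = [
    "Metadata_plate",
    "Metadata_replica",
    "Metadata_well",
    "Metadata_timepoint_h",
]
_TREATMENT_META = ["Metadata_compound", "Metadata_dose_uM", "Metadata_moa", "Metadata_role"]


def aggregate_to_well(table: ProfileTable, statistic: str = "median") -> ProfileTable:
    """Collapse tile/FOV records to one record per (plate, replica, well, timepoint).

    ``statistic`` is "median" (default, robust to single out-of-focus fields)
    or "mean".  Treatment metadata must be constant within each well group.
    Idempotent at well granularity.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"unsupported aggregation statistic {statistic!r}")
    if table.granularity == "well":
        return table

    df = table.data
    grouped = df.groupby(_WELL_GROUP, sort=True, dropna=False)
    for meta_col in _TREATMENT_META:
        n_unique = grouped[meta_col].nunique(dropna=False)
        if (n_unique > 1).any():
            bad = n_unique[n_unique > 1].index[0]
            raise IntegrityError(
                f"conflicting {meta_col} within well group {tuple(bad)}"
            )
    agg = grouped[table.feature_names].median() if statistic == "median" else grouped[
        table.feature_names
    ].mean()
    meta = grouped[_TREATMENT_META].first()
    out = pd.concat([meta, agg], axis=1).reset_index()
    out["Metadata_fov"] = pd.array([pd.NA] * len(out), dtype="Int64")
    out = out[list(METADATA_COLUMNS) + table.feature_names]
    return ProfileTable(out, list(table.feature_names), granularity="well")
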
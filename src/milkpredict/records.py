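"""Milking-session records: schema, CSV I/O, feature extraction, labels.

A :class:`MilkingRecord` holds one cow-session observation as logged by a
parlour monitoring system: per-session milk yield, average milking time
(AMT), mean flow rate over the four early windows 0-15 s, 15-30 s, 30-60 s
and 60-120 s, peak flow and peak time, removal (detachment) flow, and the
cow's average milk yield over the previous 10 days.

Features are mean-normalized: each column is divided by its own mean, so a
normalized column fitted on its own rows averages exactly 1. The two
prediction targets are binary: AMT at an 8 min cut and removal flow at a
600 g/min cut, with values at or above the cut forming the positive class.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMT",
    "REMOVAL_FLOW",
    "DEFAULT_THRESHOLDS",
    "FULL_FEATURE_SET",
    "REDUCED_FEATURE_SET",
    "SchemaError",
    "ValidationError",
    "MilkingRecord",
    "FeatureMatrix",
    "BinaryLabels",
    "read_records",
    "write_records",
    "records_to_frame",
    "frame_to_records",
    "extract_features",
    "normalize_features",
    "apply_normalization",
    "make_labels",
    "save_normalization",
    "load_normalization",
]

#: Task identifiers.
AMT = "AMT"
REMOVAL_FLOW = "REMOVAL_FLOW"

#: Default decision thresholds, in task units (min for AMT, g/min for flow).
DEFAULT_THRESHOLDS: Mapping[str, float] = {AMT: 8.0, REMOVAL_FLOW: 600.0}

#: The five model inputs available within the first two minutes of milking.
FULL_FEATURE_SET: tuple[str, ...] = (
    "avg_yield_10d",
    "flow_0_15",
    "flow_15_30",
    "flow_30_60",
    "flow_60_120",
)

#: The three-feature subset used in the reduced-dimensionality experiment.
REDUCED_FEATURE_SET: tuple[str, ...] = ("flow_15_30", "flow_30_60", "flow_60_120")


class SchemaError(ValueError):
    """A required column is missing or unknown."""


class ValidationError(ValueError):
    """Cell values violate the record invariants."""


#: numeric fields, each with (non-negative required, strictly positive required)
_NUMERIC_FIELDS: tuple[str, ...] = (
    "milk_yield",
    "amt",
    "flow_0_15",
    "flow_15_30",
    "flow_30_60",
    "flow_60_120",
    "peak_flow",
    "peak_time",
    "removal_flow",
    "avg_yield_10d",
)

_ALL_COLUMNS: tuple[str, ...] = ("cow_id", "session_time") + _NUMERIC_FIELDS


@dataclass(frozen=True)
class MilkingRecord:
    """One cow-session observation.

    Units: yields kg, times min, flow rates g/min. All flow/yield/time
    fields are non-negative; ``amt`` is strictly positive. ``peak_flow``
    is an instantaneous maximum and is *not* required to dominate the
    window averages.
    """

    cow_id: str
    session_time: str
    milk_yield: float
    amt: float
    flow_0_15: float
    flow_15_30: float
    flow_30_60: float
    flow_60_120: float
    peak_flow: float
    peak_time: float
    removal_flow: float
    avg_yield_10d: float

    def __post_init__(self) -> None:
        for name in _NUMERIC_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value!r}")
        if self.amt <= 0:
            raise ValidationError(f"amt must be strictly positive, got {self.amt!r}")


@dataclass
class FeatureMatrix:
    """n x p numeric feature table plus its normalization state.

    ``normalization_means`` is ``None`` for raw features, else the
    per-column means the values were divided by.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    normalization_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D array")
        self.feature_names = tuple(self.feature_names)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if self.normalization_means is not None:
            self.normalization_means = np.asarray(self.normalization_means, dtype=float)
            if self.normalization_means.shape != (len(self.feature_names),):
                raise ValueError("normalization_means length must equal feature count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryLabels:
    """Length-n label vector with entries in {+1, -1}."""

    values: np.ndarray
    task: str
    threshold: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.size and not np.isin(self.values, (-1, 1)).all():
            raise ValidationError("labels must be +1 or -1")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")


def records_to_frame(records: Iterable[MilkingRecord]) -> pd.DataFrame:
    """Tabulate records in canonical column order."""
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=list(_ALL_COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[MilkingRecord]:
    return [
        MilkingRecord(
            cow_id=str(row.cow_id),
            session_time=str(row.session_time),
            **{name: float(getattr(row, name)) for name in _NUMERIC_FIELDS},
        )
        for row in frame.itertuples(index=False)
    ]


def read_records(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[MilkingRecord]:
    """Read milking records from a headered CSV file.

    Parameters
    ----------
    path:
        CSV file, comma-separated, UTF-8, header required. Lines starting
        with ``#`` (provenance headers) are ignored.
    dialect:
        Optional map of canonical column name -> column name in the file,
        for ingesting vendor exports.

    Raises
    ------
    SchemaError
        A required column is absent (the message names it).
    ValidationError
        Malformed numeric cells or negative values; the message cites the
        offending data-row numbers (1-based, excluding the header).
    """
    frame = pd.read_csv(path, comment="#", encoding="utf-8")
    if dialect:
        rename = {file_col: canon for canon, file_col in dialect.items()}
        frame = frame.rename(columns=rename)
    missing = [c for c in _ALL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    frame = frame.loc[:, list(_ALL_COLUMNS)]

    numeric = frame[list(_NUMERIC_FIELDS)].apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & frame[list(_NUMERIC_FIELDS)].notna()
    empty = frame[list(_NUMERIC_FIELDS)].isna()
    bad_rows = sorted(frame.index[(bad_cells | empty).any(axis=1)] + 1)
    if bad_rows:
        raise ValidationError(f"malformed numeric cell(s) on row(s): {bad_rows}")
    negative = (numeric < 0) | ((numeric[["amt"]] <= 0).reindex(columns=numeric.columns, fill_value=False))
    neg_rows = sorted(numeric.index[negative.any(axis=1)] + 1)
    if neg_rows:
        raise ValidationError(
            f"negative (or non-positive amt) value(s) on row(s): {neg_rows}"
        )
    frame[list(_NUMERIC_FIELDS)] = numeric
    return frame_to_records(frame)


def write_records(records: Iterable[MilkingRecord], path: str | Path) -> None:
    """Write records to CSV with full float precision (round-trip safe)."""
    records_to_frame(records).to_csv(path, index=False, float_format="%.10g")


def extract_features(
    records: Sequence[MilkingRecord],
    feature_set: Sequence[str] = FULL_FEATURE_SET,
) -> FeatureMatrix:
    """Assemble the n x p raw feature matrix in the given column order."""
    feature_set = tuple(feature_set)
    if not feature_set:
        raise ValueError("feature_set must not be empty")
    unknown = [f for f in feature_set if f not in FULL_FEATURE_SET]
    if unknown:
        raise SchemaError(f"unknown feature name(s): {', '.join(unknown)}")
    values = np.array(
        [[getattr(r, f) for f in feature_set] for r in records], dtype=float
    ).reshape(len(records), len(feature_set))
    return FeatureMatrix(values=values, feature_names=feature_set)


def normalize_features(X: FeatureMatrix) -> FeatureMatrix:
    """Mean-normalize: divide each column by its own mean and record it.

    Every normalized column then has mean exactly 1 on the rows it was
    fitted on. Columns with mean <= 0 (degenerate all-zero columns, since
    all features are non-negative) raise a :class:`ValidationError`.
    """
    means = X.values.mean(axis=0)
    bad = [name for name, m in zip(X.feature_names, means) if not m > 0]
    if bad:
        raise ValidationError(f"column mean not strictly positive: {', '.join(bad)}")
    return FeatureMatrix(
        values=X.values / means,
        feature_names=X.feature_names,
        normalization_means=means,
    )


def apply_normalization(X: FeatureMatrix, means: np.ndarray) -> FeatureMatrix:
    """Divide columns by externally supplied means (e.g. training-fold means)."""
    means = np.asarray(means, dtype=float)
    if means.shape != (X.p,):
        raise ValueError(f"expected {X.p} means, got shape {means.shape}")
    if not (means > 0).all():
        raise ValidationError("normalization means must all be strictly positive")
    return FeatureMatrix(
        values=X.values / means,
        feature_names=X.feature_names,
        normalization_means=means,
    )


def make_labels(
    records: Sequence[MilkingRecord],
    task: str,
    threshold: float | None = None,
) -> BinaryLabels:
    """Binarize the task variable: value >= threshold -> +1, else -1.

    Ties at exactly the threshold are positive by convention.
    """
    if task not in (AMT, REMOVAL_FLOW):
        raise ValueError(f"unknown task {task!r}; expected {AMT} or {REMOVAL_FLOW}")
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[task]
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    field = "amt" if task == AMT else "removal_flow"
    raw = np.array([getattr(r, field) for r in records], dtype=float)
    values = np.where(raw >= threshold, 1, -1).astype(int)
    return BinaryLabels(values=values, task=task, threshold=float(threshold))


def save_normalization(X: FeatureMatrix, path: str | Path) -> None:
    """Write the normalization sidecar (feature names and means) as JSON."""
    if X.normalization_means is None:
        raise ValueError("feature matrix carries no normalization state")
    Path(path).write_text(
        json.dumps(
            {
                "feature_names": list(X.feature_names),
                "means": [float(m) for m in X.normalization_means],
            },
            indent=2,
        )
    )


def load_normalization(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    doc = json.loads(Path(path).read_text())
    return tuple(doc["feature_names"]), np.asarray(doc["means"], dtype=float)
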
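"""Reading and writing patient records in the PhysioNet-2019 ``.psv`` dialect.

One pipe-separated file per patient: a header of column names, then one row
per hour of ICU stay. Missing measurements are written as ``NaN``. The label
column (``SepsisLabel`` by default) holds the per-hour binary sepsis label,
which is absorbing in the real data (once 1, stays 1).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_LABEL_COLUMN = "SepsisLabel"


class PsvParseError(ValueError):
    """A .psv file that cannot be parsed into a patient record."""


@dataclass
class PatientRecord:
    """One patient's hourly feature matrix with missingness mask and labels.

    Attributes
    ----------
    patient_id : str
        Unique identifier (by convention the file stem).
    features : (T, d) float array
        Hourly measurements; missing cells hold NaN before preprocessing
        and 0 after.
    mask : (T, d) bool array
        True where the cell was *originally observed*.
    labels : (T,) int array
        Per-hour binary labels.
    filled : (T, d) bool array or None
        Set by imputation: True where a missing cell was filled from
        neighbouring observations (as opposed to the 0 sentinel).
    """

    patient_id: str
    features: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    filled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a T x d matrix")
        if self.features.shape[0] < 1:
            raise ValueError("record must contain at least one hourly row")
        if self.mask.shape != self.features.shape:
            raise ValueError("mask shape must match features")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels length must equal number of rows")

    @property
    def n_hours(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def copy(self) -> "PatientRecord":
        return PatientRecord(
            patient_id=self.patient_id,
            features=self.features.copy(),
            mask=self.mask.copy(),
            labels=self.labels.copy(),
            filled=None if self.filled is None else self.filled.copy(),
        )


@dataclass
class Cohort:
    """An ordered collection of patient records sharing one feature schema."""

    records: list[PatientRecord]
    feature_names: list[str]
    provenance: str = "real"  # {"real", "synthetic"}

    def __post_init__(self) -> None:
        d = len(self.feature_names)
        seen: set[str] = set()
        for rec in self.records:
            if rec.n_features != d:
                raise ValueError(
                    f"record {rec.patient_id!r} has {rec.n_features} features, "
                    f"cohort schema has {d}"
                )
            if rec.patient_id in seen:
                raise ValueError(f"duplicate patient id {rec.patient_id!r}")
            seen.add(rec.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def entity_labels(self) -> np.ndarray:
        """Per-patient class: 1 iff any hourly label is positive."""
        return np.array([int(rec.labels.any()) for rec in self.records])


def read_psv(
    path: str | os.PathLike | io.StringIO,
    label_column: str = DEFAULT_LABEL_COLUMN,
    patient_id: str | None = None,
) -> PatientRecord:
    """Parse one pipe-separated patient file into a :class:`PatientRecord`.

    Row order is preserved (it is the temporal order of the stay); the label
    column is removed from the feature matrix; the mask is False exactly
    where a cell parsed as NaN/empty.
    """
    if patient_id is None:
        patient_id = Path(path).stem if not isinstance(path, io.StringIO) else "record"
    try:
        frame = pd.read_csv(path, sep="|", header=0, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise PsvParseError(f"{patient_id}: no data rows") from None
    if frame.shape[0] == 0:
        raise PsvParseError(f"{patient_id}: no data rows")
    if label_column not in frame.columns:
        raise PsvParseError(
            f"{patient_id}: label column {label_column!r} not found "
            f"(columns: {list(frame.columns)})"
        )
    raw = frame.to_numpy()
    for i, row in enumerate(raw):
        if all(isinstance(v, float) and np.isnan(v) for v in row):
            raise PsvParseError(f"{patient_id}: blank data row at line {i + 2}")
    values = frame.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & frame.notna() & (frame != "NaN")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise PsvParseError(
            f"{patient_id}: unparseable value {raw[r, c]!r} at line {r + 2}, "
            f"column {frame.columns[c]!r}"
        )
    labels = values[label_column].to_numpy()
    if np.isnan(labels).any():
        raise PsvParseError(f"{patient_id}: missing value in label column")
    feats = values.drop(columns=[label_column])
    matrix = feats.to_numpy(dtype=float)
    mask = ~np.isnan(matrix)
    return PatientRecord(
        patient_id=patient_id,
        features=matrix,
        mask=mask,
        labels=labels.astype(int),
    )


def _check_row_widths(path: str | os.PathLike) -> None:
    """Reject ragged rows with the offending line number before pandas pads them."""
    with open(path) as fh:
        header = fh.readline()
        width = header.rstrip("\n").count("|")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if line.rstrip("\n").count("|") != width:
                raise PsvParseError(f"{path}: malformed row width at line {lineno}")


def read_psv_file(path: str | os.PathLike, label_column: str = DEFAULT_LABEL_COLUMN) -> PatientRecord:
    """:func:`read_psv` for an on-disk file, with strict row-width checking."""
    _check_row_widths(path)
    return read_psv(path, label_column=label_column)


def write_psv(
    record: PatientRecord,
    path: str | os.PathLike,
    feature_names: Sequence[str],
    label_column: str = DEFAULT_LABEL_COLUMN,
) -> None:
    """Write a record back to the ``.psv`` dialect (missing cells as ``NaN``).

    Cells that are neither observed nor imputation-filled are emitted as NaN,
    so an un-preprocessed record round-trips exactly.
    """
    if record.n_features == 0:
        raise ValueError("cannot write a record with zero feature columns")
    if len(feature_names) != record.n_features:
        raise ValueError("feature_names length must match record width")
    with open(path, "w") as fh:
        fh.write("|".join([*feature_names, label_column]) + "\n")
        for t in range(record.n_hours):
            cells = []
            for j in range(record.n_features):
                if record.filled is None and not record.mask[t, j]:
                    cells.append("NaN")
                else:
                    v = record.features[t, j]
                    cells.append("NaN" if np.isnan(v) else format(float(v), ".10g"))
            cells.append(str(int(record.labels[t])))
            fh.write("|".join(cells) + "\n")


def load_cohort(
    directory: str | os.PathLike,
    label_column: str = DEFAULT_LABEL_COLUMN,
    provenance: str = "real",
) -> Cohort:
    """Load every ``.psv`` file in a directory into one cohort.

    Files are read in sorted filename order and must share the same header;
    a mismatch is reported with the offending filename.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.psv"))
    if not paths:
        raise FileNotFoundError(f"no .psv files in {directory}")
    header0: list[str] | None = None
    records = []
    for p in paths:
        with open(p) as fh:
            header = fh.readline().rstrip("\n").split("|")
        if header0 is None:
            header0 = header
        elif header != header0:
            raise PsvParseError(f"header of {p.name} does not match {paths[0].name}")
        records.append(read_psv_file(p, label_column=label_column))
    feature_names = [c for c in header0 if c != label_column]
    return Cohort(records=records, feature_names=feature_names, provenance=provenance)


def save_cohort(cohort: Cohort, directory: str | os.PathLike, label_column: str = DEFAULT_LABEL_COLUMN) -> None:
    """Write one ``.psv`` file per record, named by patient id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in cohort:
        write_psv(rec, directory / f"{rec.patient_id}.psv", cohort.feature_names, label_column)
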
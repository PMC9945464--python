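"""Imputation and [1, 6] rescaling of hourly ICU records.

Missing measurements are filled in three steps of decreasing information:
a gap bracketed by observations on both sides takes the mean of the nearest
preceding and subsequent observed values; a trailing gap carries the most
recent observation forward; anything left (leading gaps, all-missing
columns) becomes 0. Observed and neighbour-filled values are then rescaled
feature-wise onto [1, 6], so that 0 unambiguously marks "missing" and all
features share one range.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .psv_io import Cohort, PatientRecord

TARGET_LO = 1.0
TARGET_HI = 6.0
MISSING_SENTINEL = 0.0
DEGENERATE_MIDPOINT = 0.5 * (TARGET_LO + TARGET_HI)  # 3.5


def impute_record(record: PatientRecord) -> PatientRecord:
    """Fill missing cells; returns a new record with ``filled`` set.

    ``mask`` still marks the originally observed cells (scaling statistics
    use only those); ``filled`` marks cells imputed from neighbouring
    observations. Cells with neither flag hold the 0 sentinel.
    """
    rec = record.copy()
    T, d = rec.features.shape
    filled = np.zeros((T, d), dtype=bool)
    for j in range(d):
        col = rec.features[:, j]
        obs = np.flatnonzero(rec.mask[:, j])
        if obs.size == 0:
            col[:] = MISSING_SENTINEL
            continue
        missing = np.flatnonzero(~rec.mask[:, j])
        for t in missing:
            prev = obs[obs < t]
            nxt = obs[obs > t]
            if prev.size and nxt.size:
                col[t] = 0.5 * (col[prev[-1]] + col[nxt[0]])
                filled[t, j] = True
            elif prev.size:
                col[t] = col[prev[-1]]
                filled[t, j] = True
            else:
                col[t] = MISSING_SENTINEL
    rec.filled = filled
    return rec


@dataclass
class ScalingParams:
    """Per-feature min/max fitted on originally observed training cells."""

    observed_min: np.ndarray
    observed_max: np.ndarray
    degenerate: np.ndarray  # True where max == min or no observations
    target_lo: float = TARGET_LO
    target_hi: float = TARGET_HI

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "observed_min": self.observed_min.tolist(),
            "observed_max": self.observed_max.tolist(),
            "degenerate": self.degenerate.astype(bool).tolist(),
            "target_lo": self.target_lo,
            "target_hi": self.target_hi,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ScalingParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            observed_min=np.asarray(payload["observed_min"], dtype=float),
            observed_max=np.asarray(payload["observed_max"], dtype=float),
            degenerate=np.asarray(payload["degenerate"], dtype=bool),
            target_lo=payload["target_lo"],
            target_hi=payload["target_hi"],
        )


def fit_scaling(cohort: Cohort) -> ScalingParams:
    """Fit per-feature min/max over originally observed cells only.

    Features with no observations, or a constant observed value, are
    flagged degenerate; their observed cells later map to the midpoint.
    Fit on the training split only, then apply to held-out data.
    """
    d = len(cohort.feature_names)
    lo = np.zeros(d)
    hi = np.zeros(d)
    degen = np.zeros(d, dtype=bool)
    for j in range(d):
        vals = np.concatenate(
            [rec.features[rec.mask[:, j], j] for rec in cohort.records]
        )
        if vals.size == 0:
            degen[j] = True
        else:
            lo[j], hi[j] = vals.min(), vals.max()
            if lo[j] == hi[j]:
                degen[j] = True
    return ScalingParams(observed_min=lo, observed_max=hi, degenerate=degen)


def apply_scaling(record: PatientRecord, params: ScalingParams) -> PatientRecord:
    """Map observed and neighbour-filled cells onto [1, 6]; keep 0 for missing.

    x -> lo + (hi - lo) * (x - min) / (max - min), clipped to [lo, hi] for
    out-of-range held-out values; degenerate features map to the midpoint.
    """
    rec = record.copy()
    if rec.filled is None:
        raise ValueError("record must be imputed before scaling (call impute_record)")
    scalable = rec.mask | rec.filled
    span = params.target_hi - params.target_lo
    for j in range(rec.n_features):
        sel = scalable[:, j]
        if not sel.any():
            continue
        if params.degenerate[j]:
            rec.features[sel, j] = DEGENERATE_MIDPOINT
            continue
        rng = params.observed_max[j] - params.observed_min[j]
        x = rec.features[sel, j]
        y = params.target_lo + span * (x - params.observed_min[j]) / rng
        rec.features[sel, j] = np.clip(y, params.target_lo, params.target_hi)
    rec.features[~scalable] = MISSING_SENTINEL
    return rec


def preprocess_cohort(
    cohort: Cohort, params: ScalingParams | None = None
) -> tuple[Cohort, ScalingParams]:
    """Impute every record, fit scaling if not given, and apply it."""
    imputed = Cohort(
        records=[impute_record(r) for r in cohort.records],
        feature_names=list(cohort.feature_names),
        provenance=cohort.provenance,
    )
    if params is None:
        params = fit_scaling(imputed)
    scaled = Cohort(
        records=[apply_scaling(r, params) for r in imputed.records],
        feature_names=list(cohort.feature_names),
        provenance=cohort.provenance,
    )
    return scaled, params
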
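"""Label-shift construction for early-detection training.

A non-temporal classifier can be taught to fire *before* clinical sepsis
onset by re-pairing each hourly feature vector r_t with a future label
l_{t+c}. With absorbing labels this tags the c hours preceding onset as
positive, so the model learns to associate pre-onset physiology with the
eventual diagnosis. The canonical shifts are c = 1, 6 and 12 hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psv_io import Cohort

DEFAULT_SHIFTS = (1, 6, 12)


@dataclass
class ShiftedDataset:
    """Flat per-row table (patient_id, t, features..., label l_{t+c})."""

    shift_c: int
    frame: pd.DataFrame  # columns: patient_id, t, <feature names...>, label
    feature_names: list[str]
    policy: str = "clamp"

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def to_psv(self, path) -> None:
        self.frame.to_csv(path, sep="|", index=False)


def shift_labels(cohort: Cohort, c: int, policy: str = "clamp") -> ShiftedDataset:
    """Pair each row r_t with the label l_{t+c}.

    When t+c runs past the patient's last hour, ``clamp`` (default) pairs
    r_t with the final label l_T — correct for absorbing sepsis labels —
    while ``drop`` removes the row. c = 0 reproduces the original pairing.
    """
    if c < 0:
        raise ValueError(f"shift must be non-negative, got {c}")
    if policy not in ("clamp", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    chunks = []
    for rec in cohort:
        T = rec.n_hours
        if policy == "clamp":
            idx = np.minimum(np.arange(T) + c, T - 1)
            keep = np.arange(T)
        else:
            keep = np.arange(max(T - c, 0))
            idx = keep + c
        if keep.size == 0:
            continue
        block = pd.DataFrame(rec.features[keep], columns=cohort.feature_names)
        block.insert(0, "patient_id", rec.patient_id)
        block.insert(1, "t", keep)
        block["label"] = rec.labels[idx]
        chunks.append(block)
    frame = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=["patient_id", "t", *cohort.feature_names, "label"])
    )
    return ShiftedDataset(
        shift_c=c, frame=frame, feature_names=list(cohort.feature_names), policy=policy
    )


def build_shift_suite(
    cohort: Cohort,
    shifts: tuple[int, ...] | list[int] = DEFAULT_SHIFTS,
    policy: str = "clamp",
) -> list[ShiftedDataset]:
    """One shifted dataset per value of c, in the order given."""
    if len(shifts) == 0:
        raise ValueError("shifts must be non-empty")
    if len(set(shifts)) != len(shifts):
        raise ValueError(f"duplicate shifts in {list(shifts)}")
    return [shift_labels(cohort, c, policy=policy) for c in shifts]
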
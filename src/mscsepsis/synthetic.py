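"""Synthetic ICU cohorts with planted sepsis effects.

Emulates the structural quirks of hourly sepsis records — variable-length
stays, heavy per-feature missingness, absorbing per-hour labels, and strong
class imbalance (septic prevalence ~7.3%) — with a known, recoverable
generative mechanism: a configurable subset of "driver" features whose mean
steps up by Δ from the onset hour in septic patients. Everything else is
exchangeable noise, so any feature an interpretation method ranks highly
that is not a driver is a false positive by construction.

Values are generated directly on the [1, 6] preprocessing scale (missing
cells as NaN), so cohorts can either bypass preprocessing or exercise it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psv_io import Cohort, PatientRecord

#: septic / total patient counts in the public sepsis challenge data
DEFAULT_PREVALENCE = 2932 / (2932 + 37404)


@dataclass
class SynthConfig:
    n_patients: int = 200
    prevalence: float = DEFAULT_PREVALENCE
    d: int = 40
    stay_hours: tuple[int, int] = (8, 60)       # uniform inclusive range
    min_onset: int = 4                          # earliest possible onset hour
    drivers: tuple[int, ...] = (0, 1, 2)
    delta: float = 1.5                          # post-onset mean shift, scaled units
    missing_rate: float = 0.2                   # per-cell Bernoulli missingness
    noise_sd: float = 0.5                       # hourly measurement noise
    patient_sd: float = 0.3                     # per-patient baseline offset
    baseline_mean: float = 3.0                  # population mean on the [1,6] scale
    ar1: float = 0.0                            # optional AR(1) noise correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence < 1:
            raise ValueError("prevalence must lie in [0, 1)")
        if self.d < 1 or self.n_patients < 1:
            raise ValueError("d and n_patients must be positive")
        if any(not 0 <= f < self.d for f in self.drivers):
            raise ValueError("driver indices must lie in [0, d)")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.stay_hours[0] < 1 or self.stay_hours[0] > self.stay_hours[1]:
            raise ValueError("invalid stay_hours range")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")


def generate_cohort(config: SynthConfig) -> Cohort:
    """Draw a fully reproducible synthetic cohort from the config's seed.

    Per patient: stay length T ~ U{min, max}; septic status ~
    Bernoulli(prevalence); for septic patients an onset hour is drawn
    uniformly from [min_onset, T-1] and driver features shift by +Δ from
    onset; labels are 0 before onset and 1 from onset on (absorbing);
    missingness is applied last as NaN + mask.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.stay_hours
    records = []
    feature_names = [f"F{j:02d}" for j in range(config.d)]
    for i in range(config.n_patients):
        T = int(rng.integers(lo, hi + 1))
        septic = bool(rng.random() < config.prevalence)
        baseline = config.baseline_mean + config.patient_sd * rng.standard_normal(config.d)
        eps = config.noise_sd * rng.standard_normal((T, config.d))
        if config.ar1 > 0:
            for t in range(1, T):
                eps[t] = config.ar1 * eps[t - 1] + np.sqrt(1 - config.ar1**2) * eps[t]
        X = baseline[None, :] + eps
        labels = np.zeros(T, dtype=int)
        if septic:
            onset = int(rng.integers(min(config.min_onset, T - 1), T))
            labels[onset:] = 1
            for f in config.drivers:
                X[onset:, f] += config.delta
        X = np.clip(X, 1.0, 6.0)
        mask = rng.random((T, config.d)) >= config.missing_rate
        X = np.where(mask, X, np.nan)
        records.append(
            PatientRecord(patient_id=f"p{i:05d}", features=X, mask=mask, labels=labels)
        )
    return Cohort(records=records, feature_names=feature_names, provenance="synthetic")


@dataclass
class ThresholdOracleSpec:
    """A transparent stand-in black box: alarm when one feature crosses a
    threshold, absorbing from the first crossing onward."""

    feature_index: int
    threshold: float
    direction: str = "above"  # {"above", "below"}
    persistence: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError(f"unknown direction {self.direction!r}")


def make_threshold_oracle(spec: ThresholdOracleSpec, d: int | None = None):
    """Build a deterministic per-row labelling Oracle from the spec."""
    from .interpret import Oracle

    def _label(record: PatientRecord) -> np.ndarray:
        if spec.feature_index >= record.n_features:
            raise IndexError(
                f"oracle feature index {spec.feature_index} out of range "
                f"for record with {record.n_features} features"
            )
        x = record.features[:, spec.feature_index]
        with np.errstate(invalid="ignore"):
            hit = x > spec.threshold if spec.direction == "above" else x < spec.threshold
        hit = np.where(np.isnan(x), False, hit)
        if spec.persistence:
            hit = np.maximum.accumulate(hit)
        return hit.astype(int)

    name = f"threshold[{spec.feature_index}{'>' if spec.direction == 'above' else '<'}{spec.threshold}]"
    return Oracle(label_fn=_label, name=name, deterministic=True)


def generate_planted_clusters(
    k: int,
    points_per_cluster: int,
    separation: float,
    spread: float,
    seed: int = 0,
    d: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs with pairwise-separated centers; returns (points, labels).

    Centers sit at ``separation``-scaled standard-basis vectors (pairwise
    distance separation * sqrt(2) >= separation), in ``d`` dimensions
    (default k). With spread = 0 every point coincides with its center.
    """
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if separation <= 0:
        raise ValueError("separation must be positive")
    d = d if d is not None else k
    if d < k:
        raise ValueError("dimension must be >= k to place separated centers")
    rng = np.random.default_rng(seed)
    centers = separation * np.eye(d)[:k]
    points = np.vstack(
        [c + spread * rng.standard_normal((points_per_cluster, d)) for c in centers]
    )
    labels = np.repeat(np.arange(k), points_per_cluster)
    return points, labels
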
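"""Evaluation metrics: confusion-matrix measures, the 2019 sepsis-challenge
utility score, the rank-sum feature screen, and the five-number summary table.

The utility score rewards each patient-hour of a prediction sequence with a
piecewise-linear function of time relative to sepsis onset: alarms raised in
the 12 hours before onset earn increasing credit, peaking 6 hours before
onset and held through 3 hours after; missed positive hours are penalized,
as is every false alarm on a non-septic patient. The total is normalized so
that the utility-maximizing predictor scores 1 and the silent (never-alarm)
predictor scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .psv_io import Cohort


# ---------------------------------------------------------------------------
# confusion-matrix metrics


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    specificity: float
    recall: float
    f1: float
    mcc: float
    undefined: list[str] = field(default_factory=list)
    utility_raw: float | None = None
    utility_normalized: float | None = None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "specificity": self.specificity, "recall": self.recall,
            "f1": self.f1, "mcc": self.mcc, "undefined": self.undefined,
            "utility_raw": self.utility_raw,
            "utility_normalized": self.utility_normalized,
        }


def confusion_metrics(pred, truth) -> MetricsReport:
    """Accuracy, precision, specificity, recall, F1 and Matthews coefficient.

    Ratios with a zero denominator are reported as 0 and listed in
    ``undefined`` rather than raising.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / pred.size
    precision = ratio(tp, tp + fp, "precision")
    specificity = ratio(tn, tn + fp, "specificity")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(tp, fp, tn, fn, accuracy, precision, specificity,
                         recall, f1, float(mcc), undefined)


# ---------------------------------------------------------------------------
# challenge utility score


@dataclass
class UtilityConfig:
    """Reward geometry of the early-warning utility score.

    Hours are measured relative to sepsis onset t_sepsis. A true alarm earns
    a reward ramping linearly from 0 at t_sepsis - early_window up to
    ``max_u_tp`` at t_sepsis - optimal_offset, then back down to 0 at
    t_sepsis + late_window; an unflagged positive hour after the optimum
    ramps down to ``min_u_fn``; every false alarm costs ``u_fp`` and a true
    negative earns ``u_tn``. By the labelling convention of the source data,
    per-hour positive labels begin ``optimal_offset`` hours *before*
    clinical onset, so onset is recovered from a label sequence as
    first-positive-hour + optimal_offset.
    """

    early_window: float = 12.0
    optimal_offset: float = 6.0
    late_window: float = 3.0
    max_u_tp: float = 1.0
    min_u_fn: float = -2.0
    u_fp: float = -0.05
    u_tn: float = 0.0

    def __post_init__(self) -> None:
        if self.optimal_offset > self.early_window:
            raise ValueError("optimal_offset must not exceed early_window")

    # signed offsets relative to onset, matching the piecewise breakpoints
    @property
    def dt_early(self) -> float:
        return -self.early_window

    @property
    def dt_optimal(self) -> float:
        return -self.optimal_offset

    @property
    def dt_late(self) -> float:
        return self.late_window


def _patient_utility(labels: np.ndarray, predictions: np.ndarray, cfg: UtilityConfig) -> float:
    """Raw utility of one patient's hourly prediction sequence."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("prediction/label length mismatch for patient")
    n = labels.size
    if np.any(labels):
        is_septic = True
        t_sepsis = float(np.argmax(labels)) - cfg.dt_optimal
    else:
        is_septic = False
        t_sepsis = np.inf

    m_1 = cfg.max_u_tp / (cfg.dt_optimal - cfg.dt_early)
    b_1 = -m_1 * cfg.dt_early
    m_2 = -cfg.max_u_tp / (cfg.dt_late - cfg.dt_optimal)
    b_2 = -m_2 * cfg.dt_late
    m_3 = cfg.min_u_fn / (cfg.dt_late - cfg.dt_optimal)
    b_3 = -m_3 * cfg.dt_optimal

    u = 0.0
    for t in range(n):
        if t > t_sepsis + cfg.dt_late:
            continue
        rel = t - t_sepsis
        if is_septic and predictions[t]:
            if rel <= cfg.dt_optimal:
                u += max(m_1 * rel + b_1, cfg.u_fp)
            else:
                u += m_2 * rel + b_2
        elif is_septic and not predictions[t]:
            if rel > cfg.dt_optimal:
                u += m_3 * rel + b_3
        elif predictions[t]:
            u += cfg.u_fp
        else:
            u += cfg.u_tn
    return u


def optimal_predictions(labels: np.ndarray, cfg: UtilityConfig | None = None) -> np.ndarray:
    """The utility-maximizing alarm sequence for one patient.

    Septic patients are flagged from the first rewarded hour,
    t_sepsis - early_window, onward; non-septic patients are never flagged.
    """
    cfg = cfg or UtilityConfig()
    labels = np.asarray(labels, dtype=int)
    best = np.zeros(labels.size, dtype=int)
    if np.any(labels):
        t_sepsis = float(np.argmax(labels)) - cfg.dt_optimal
        start = int(max(0, np.ceil(t_sepsis + cfg.dt_early)))
        best[start:] = 1
    return best


def utility_score(
    predictions: list[np.ndarray],
    labels: list[np.ndarray],
    config: UtilityConfig | None = None,
) -> tuple[float, float]:
    """(raw, normalized) utility over a cohort of hourly prediction sequences.

    normalized = (U - U_silent) / (U_optimal - U_silent), so the optimal
    predictor scores exactly 1 and the never-alarm predictor exactly 0.
    """
    cfg = config or UtilityConfig()
    if len(predictions) != len(labels):
        raise ValueError("one prediction sequence per patient required")
    raw = opt = silent = 0.0
    for pred, lab in zip(predictions, labels):
        raw += _patient_utility(lab, pred, cfg)
        opt += _patient_utility(lab, optimal_predictions(lab, cfg), cfg)
        silent += _patient_utility(lab, np.zeros(len(lab), dtype=int), cfg)
    if opt == silent:
        raise ValueError("degenerate cohort: optimal and silent utilities coincide")
    return raw, (raw - silent) / (opt - silent)


# ---------------------------------------------------------------------------
# feature screening


def ranksum_screen(cohort: Cohort, alpha: float = 0.05) -> dict[str, dict]:
    """Two-sided Wilcoxon rank-sum test per feature, sepsis vs non-sepsis.

    Pools *originally observed* cells of each feature by entity class
    (patient septic iff any hourly label is 1). Raw p-values, no
    multiplicity correction; a feature with fewer than 2 observations in
    either class is flagged untestable.
    """
    classes = cohort.entity_labels()
    if classes.min() == classes.max():
        raise ValueError("rank-sum screen needs both classes present")
    out: dict[str, dict] = {}
    for j, name in enumerate(cohort.feature_names):
        groups = {0: [], 1: []}
        for rec, k in zip(cohort.records, classes):
            groups[int(k)].append(rec.features[rec.mask[:, j], j])
        g0 = np.concatenate(groups[0]) if groups[0] else np.array([])
        g1 = np.concatenate(groups[1]) if groups[1] else np.array([])
        if g0.size < 2 or g1.size < 2:
            out[name] = {"p_value": np.nan, "significant": False, "testable": False}
            continue
        if np.ptp(np.concatenate([g0, g1])) == 0:
            out[name] = {"p_value": 1.0, "significant": False, "testable": False}
            continue
        stat, p = stats.ranksums(g1, g0)
        out[name] = {
            "p_value": float(p),
            "significant": bool(p < alpha),
            "testable": True,
            "statistic": float(stat),
        }
    return out


def quintile_table(cohort: Cohort, features: list[str] | None = None) -> dict[str, dict]:
    """Per-feature, per-class {min, Q1, median, Q3, max}.

    Computed over *all* cells, including zero-filled missing ones — on the
    [1, 6] scale a minimum of 0 therefore reads as "this feature has missing
    hours in this class". Quartiles use linear interpolation.
    """
    features = features if features is not None else list(cohort.feature_names)
    classes = cohort.entity_labels()
    out: dict[str, dict] = {}
    for name in features:
        j = cohort.feature_names.index(name)
        per_class = {}
        for k in (0, 1):
            cells = [rec.features[:, j] for rec, c in zip(cohort.records, classes) if c == k]
            if not cells:
                per_class[k] = {"flagged_empty": True}
                continue
            v = np.concatenate(cells)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            per_class[k] = {
                "min": float(v.min()), "q1": float(q1), "median": float(med),
                "q3": float(q3), "max": float(v.max()), "flagged_empty": False,
            }
        out[name] = per_class
    return out
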
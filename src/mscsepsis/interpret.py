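"""Global interpretation of black-box sepsis classifiers via MSC surrogates.

Any label source — ground truth, a clinician, or a black-box model's
per-hour predictions — is an *oracle*. Training MSC on an oracle's labels
instead of ground truth yields a *hybrid model* whose class profiles
approximate what the oracle has learned: the profiles say which anchor
patterns the oracle's "sepsis" class over-expresses. Because anchors are
points in the original feature space, the profile contrast can be pushed
back to individual clinical features and ranked.

The surrogate's worth is measured by *fidelity*: its agreement with the
oracle's own labels on held-out patients (accuracy computed against the
oracle instead of ground truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .msc import MSCConfig, MSCModel, select_anchors, train_msc, predict
from .psv_io import Cohort, PatientRecord


@dataclass
class Oracle:
    """A per-row label source: record -> length-T {0,1} vector."""

    label_fn: Callable[[PatientRecord], np.ndarray]
    name: str = "oracle"
    deterministic: bool = True

    def __call__(self, record: PatientRecord) -> np.ndarray:
        labels = np.asarray(self.label_fn(record), dtype=int)
        if labels.shape != (record.n_hours,):
            raise ValueError(
                f"oracle {self.name!r} returned {labels.shape} labels for a "
                f"{record.n_hours}-hour record"
            )
        return labels


def ground_truth_oracle() -> Oracle:
    """The identity oracle: echoes the record's own labels."""
    return Oracle(label_fn=lambda rec: rec.labels, name="ground_truth")


@dataclass
class HybridModel:
    """An MSC trained on an oracle's labels; acts as the interpretation
    mechanism for that oracle."""

    msc: MSCModel
    oracle_name: str
    fidelity: float
    accuracy_vs_ground_truth: float
    eval_entity_ids: list[str] = field(default_factory=list)
    eval_predictions: np.ndarray | None = None


def fidelity(predictions, oracle_labels) -> float:
    """Agreement rate between surrogate predictions and oracle labels."""
    predictions = np.asarray(predictions, dtype=int)
    oracle_labels = np.asarray(oracle_labels, dtype=int)
    if predictions.size == 0:
        raise ValueError("empty prediction vector")
    if predictions.shape != oracle_labels.shape:
        raise ValueError("predictions and oracle labels must have equal length")
    return float(np.mean(predictions == oracle_labels))


def _entity_stream(cohort: Cohort, classes: np.ndarray) -> list[tuple[str, int, np.ndarray]]:
    return [
        (rec.patient_id, int(k), rec.features) for rec, k in zip(cohort.records, classes)
    ]


def make_hybrid(
    cohort: Cohort,
    oracle: Oracle,
    msc_config: MSCConfig | None = None,
    seed: int = 0,
    anchor_k: int | None = 10,
    anchor_sample: int = 4000,
    test_fraction: float = 0.3,
) -> HybridModel:
    """Train an MSC surrogate on the oracle's labels and score it held-out.

    The oracle labels every hourly row; a patient is assigned to class 1
    iff any of their oracle labels is 1 (same convention as ground truth).
    Anchors are selected from a seeded subsample of training rows —
    ``anchor_k=10`` reproduces the benchmark configuration, ``anchor_k=None``
    runs the silhouette sweep. Fidelity (vs the oracle) and accuracy (vs
    ground truth) are both computed on the held-out patient split.
    """
    from .pipeline import split_cohort

    config = msc_config or MSCConfig(seed=seed)
    oracle_rows = [oracle(rec) for rec in cohort.records]
    oracle_classes = np.array([int(lab.any()) for lab in oracle_rows])
    truth_classes = cohort.entity_labels()
    for k in (0, 1):
        if not np.any(oracle_classes == k):
            warnings.warn(
                f"oracle {oracle.name!r} assigned no entity to class {k}; "
                f"class-{k} profiles remain at initialization",
                stacklevel=2,
            )

    train_idx, test_idx = split_cohort(
        cohort, test_fraction=test_fraction, seed=seed, classes=oracle_classes,
        return_indices=True,
    )
    train_records = [cohort.records[i] for i in train_idx]
    rows = np.vstack([rec.features for rec in train_records])
    rng = np.random.default_rng(seed)
    if rows.shape[0] > anchor_sample:
        rows = rows[rng.choice(rows.shape[0], anchor_sample, replace=False)]
    anchor_set = select_anchors(rows, seed=seed, fixed_k=anchor_k)

    entities = [
        (cohort.records[i].patient_id, int(oracle_classes[i]), cohort.records[i].features)
        for i in train_idx
    ]
    model = train_msc(entities, anchor_set, config)

    preds = np.array([predict(model, cohort.records[i].features) for i in test_idx])
    fid = fidelity(preds, oracle_classes[test_idx])
    acc = float(np.mean(preds == truth_classes[test_idx]))
    return HybridModel(
        msc=model,
        oracle_name=oracle.name,
        fidelity=fid,
        accuracy_vs_ground_truth=acc,
        eval_entity_ids=[cohort.records[i].patient_id for i in test_idx],
        eval_predictions=preds,
    )


# ---------------------------------------------------------------------------
# profile contrast and feature attribution


def _averaged_profile(model: MSCModel, class_k: int) -> np.ndarray:
    """One histogram per class: the absorbed-count-weighted mean of its
    (sub-)profiles, or the plain mean if nothing was absorbed."""
    plist = model.profiles[class_k]
    weights = np.array([p.n_absorbed for p in plist], dtype=float)
    P = np.vstack([p.mean_fingerprint for p in plist])
    if weights.sum() == 0:
        return P.mean(axis=0)
    return weights @ P / weights.sum()


def contrast_profiles(model: MSCModel | HybridModel) -> np.ndarray:
    """Per-anchor salience: sepsis-profile minus non-sepsis-profile
    proportions. Entries of the difference of two normalized histograms sum
    to ~0; positive entries mark anchors over-expressed in the sepsis class.
    """
    msc = model.msc if isinstance(model, HybridModel) else model
    for k in (0, 1):
        if k not in msc.profiles or not msc.profiles[k]:
            raise ValueError(f"model has no class-{k} profile")
    return _averaged_profile(msc, 1) - _averaged_profile(msc, 0)


@dataclass
class AttributionReport:
    anchor_salience: np.ndarray
    feature_scores: np.ndarray
    ranked_features: list[str]
    top_features: list[str]
    class_mixtures: dict[int, np.ndarray]
    standardized: bool = False

    def to_tsv(self, path, feature_names: list[str]) -> None:
        order = {f: r for r, f in enumerate(self.ranked_features)}
        with open(path, "w") as fh:
            fh.write("feature\tscore\trank\n")
            for f, s in sorted(
                zip(feature_names, self.feature_scores), key=lambda fs: order[fs[0]]
            ):
                fh.write(f"{f}\t{s:.6g}\t{order[f]}\n")


def attribute_features(
    model: MSCModel | HybridModel,
    feature_names: list[str],
    salience: np.ndarray | None = None,
    top_m: int | None = None,
    standardize: bool = False,
) -> AttributionReport:
    """Push the profile contrast back to clinical features and rank them.

    Each class's profile is a mixture over anchors; the class-conditional
    anchor mixture m_k = sum_i cp_{k,i} q̂_i is that mixture's centroid in
    feature space. The score of feature f is |m_{1,f} - m_{0,f}|: how far
    the sepsis and non-sepsis centroids disagree on f. With
    ``standardize=True`` the difference is divided by the per-feature
    spread (std) of anchor values, making features with very different
    anchor variance comparable; raw is the default since all features share
    the [1, 6] scale.
    """
    msc = model.msc if isinstance(model, HybridModel) else model
    anchors = msc.anchor_set.anchors
    if anchors.shape[1] != len(feature_names):
        raise ValueError("feature_names length must match anchor dimension")
    if salience is None:
        salience = contrast_profiles(msc)
    mixtures = {k: _averaged_profile(msc, k) @ anchors for k in (0, 1)}
    diff = np.abs(mixtures[1] - mixtures[0])
    if standardize:
        spread = anchors.std(axis=0, ddof=0)
        diff = np.where(spread > 0, diff / np.where(spread > 0, spread, 1.0), 0.0)
    order = np.argsort(-diff, kind="stable")
    ranked = [feature_names[i] for i in order]
    d = len(feature_names)
    if top_m is None:
        top_m = d
    elif top_m > d:
        warnings.warn(f"top_m={top_m} exceeds {d} features; clipping", stacklevel=2)
        top_m = d
    return AttributionReport(
        anchor_salience=np.asarray(salience, dtype=float),
        feature_scores=diff,
        ranked_features=ranked,
        top_features=ranked[:top_m],
        class_mixtures=mixtures,
        standardized=standardize,
    )


def plot_profiles(
    models: list[MSCModel | HybridModel],
    out: str,
    model_names: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> None:
    """Grouped bar chart of per-anchor class-profile proportions per model,
    with an overlay panel tracing each anchor across features."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mscs = [m.msc if isinstance(m, HybridModel) else m for m in models]
    if model_names is None:
        model_names = [
            m.oracle_name if isinstance(m, HybridModel) else f"model{i}"
            for i, m in enumerate(models)
        ]
    fig, axes = plt.subplots(
        len(mscs) + 1, 1, figsize=(10, 3 * (len(mscs) + 1)), constrained_layout=True
    )
    axes = np.atleast_1d(axes)
    for ax, msc, name in zip(axes[:-1], mscs, model_names):
        n = msc.anchor_set.n_anchors
        x = np.arange(n)
        width = 0.38
        for off, (k, lbl) in zip((-width / 2, width / 2), ((0, "non-sepsis"), (1, "sepsis"))):
            ax.bar(x + off, _averaged_profile(msc, k), width, label=lbl)
        ax.set_xticks(x, [f"A{i}" for i in x])
        ax.set_ylabel("proportion")
        ax.set_title(f"class profiles — {name}")
        ax.legend()
    ax = axes[-1]
    anchors = mscs[0].anchor_set.anchors
    for i, q in enumerate(anchors):
        ax.plot(q, label=f"A{i}", alpha=0.8)
    d = anchors.shape[1]
    if feature_names is not None and d <= 45:
        ax.set_xticks(range(d), feature_names, rotation=90, fontsize=6)
    ax.set_ylabel("scaled value")
    ax.set_title("anchor vectors across features")
    ax.legend(ncol=5, fontsize=7)
    fig.savefig(out, dpi=120)
    plt.close(fig)
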
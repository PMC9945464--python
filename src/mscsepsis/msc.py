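"""The Multi-set Classifier (MSC).

MSC treats each patient as a *multi-set* of hourly feature vectors rather
than a single point. A small vocabulary of representative vectors — the
*anchors* — is learned by clustering a sample of the preprocessed feature
space (kmeans++, with a silhouette sweep over the number of clusters).
Each patient is then summarised as a *fingerprint*: the normalized
histogram of nearest-anchor assignments over their hourly rows. A *class
profile* is the running mean of the fingerprints pooled within one class;
prediction assigns a new patient to the class of the nearest profile.

Because anchors live in the original (scaled) feature space and profiles
are low-dimensional histograms over them, the trained model is directly
inspectable: contrasting the sepsis and non-sepsis profiles shows which
base patterns each class over-expresses.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


@dataclass
class AnchorSet:
    """Learned base-pattern vectors plus the silhouette evidence for |Q̂|."""

    anchors: np.ndarray  # (n_anchors, d), scaled feature units
    chosen_k: int
    silhouette_by_k: dict[int, float]
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.anchors.ndim != 2 or self.anchors.shape[0] < 1:
            raise ValueError("anchors must be a non-empty 2-D matrix")

    @property
    def n_anchors(self) -> int:
        return self.anchors.shape[0]


@dataclass
class Fingerprint:
    """A patient's normalized histogram over the anchors.

    Integer per-anchor counts are the source of truth; proportions are
    always counts / n, so the histogram stays exactly normalized while the
    per-update arithmetic f = p*n + 1, n += 1, p = f/n holds for the
    matched component.
    """

    counts: np.ndarray  # (n_anchors,) integer assignment counts
    entity_id: str = ""
    class_k: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        n = self.n
        if n == 0:
            return np.zeros(len(self.counts))
        return self.counts / n

    @classmethod
    def empty(cls, n_anchors: int, entity_id: str = "", class_k: int | None = None) -> "Fingerprint":
        return cls(np.zeros(n_anchors, dtype=np.int64), entity_id=entity_id, class_k=class_k)


@dataclass
class ClassProfile:
    """Running mean of the fingerprints absorbed by one class (or sub-profile)."""

    mean_fingerprint: np.ndarray
    n_absorbed: int
    class_k: int
    profile_index: int = 0

    def __post_init__(self) -> None:
        self.mean_fingerprint = np.asarray(self.mean_fingerprint, dtype=float)


@dataclass
class MSCConfig:
    profiles_per_class: int = 1
    update_granularity: str = "per_row"  # {"per_row", "per_entity"}
    init_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.update_granularity not in ("per_row", "per_entity"):
            raise ValueError(f"unknown granularity {self.update_granularity!r}")
        if not 0 <= self.init_fraction < 1:
            raise ValueError("init_fraction must lie in [0, 1)")
        if self.profiles_per_class < 1:
            raise ValueError("profiles_per_class must be >= 1")


@dataclass
class MSCModel:
    anchor_set: AnchorSet
    profiles: dict[int, list[ClassProfile]]
    config: MSCConfig
    fingerprints: dict[str, Fingerprint] = field(default_factory=dict)

    def class_profile_matrix(self, class_k: int) -> np.ndarray:
        return np.vstack([p.mean_fingerprint for p in self.profiles[class_k]])

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "anchors": self.anchor_set.anchors.tolist(),
            "chosen_k": self.anchor_set.chosen_k,
            "silhouette_by_k": {str(k): v for k, v in self.anchor_set.silhouette_by_k.items()},
            "distance": self.anchor_set.distance,
            "profiles": {
                str(k): [
                    {
                        "mean_fingerprint": p.mean_fingerprint.tolist(),
                        "n_absorbed": p.n_absorbed,
                        "profile_index": p.profile_index,
                    }
                    for p in plist
                ]
                for k, plist in self.profiles.items()
            },
            "config": {
                "profiles_per_class": self.config.profiles_per_class,
                "update_granularity": self.config.update_granularity,
                "init_fraction": self.config.init_fraction,
                "seed": self.config.seed,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "MSCModel":
        with open(path) as fh:
            payload = json.load(fh)
        anchor_set = AnchorSet(
            anchors=np.asarray(payload["anchors"], dtype=float),
            chosen_k=payload["chosen_k"],
            silhouette_by_k={int(k): v for k, v in payload["silhouette_by_k"].items()},
            distance=payload["distance"],
        )
        profiles = {
            int(k): [
                ClassProfile(
                    mean_fingerprint=np.asarray(p["mean_fingerprint"], dtype=float),
                    n_absorbed=p["n_absorbed"],
                    class_k=int(k),
                    profile_index=p["profile_index"],
                )
                for p in plist
            ]
            for k, plist in payload["profiles"].items()
        }
        return cls(anchor_set=anchor_set, profiles=profiles, config=MSCConfig(**payload["config"]))


# ---------------------------------------------------------------------------
# anchor selection


def select_anchors(
    sample: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    fixed_k: int | None = None,
) -> AnchorSet:
    """Choose anchors as kmeans++ cluster centers of a feature-space sample.

    Sweeps k over [k_min, k_max], scoring each clustering with the mean
    silhouette coefficient, and keeps the centers of the best k (ties break
    to the smallest k). ``fixed_k`` skips the sweep and clusters once with
    that many centers — the configuration used for the sepsis benchmark is
    10 anchors.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2:
        raise ValueError("sample must be a 2-D matrix of feature vectors")
    n = sample.shape[0]
    n_distinct = np.unique(sample, axis=0).shape[0]
    if n_distinct < 2:
        raise ValueError("degenerate sample: all feature vectors identical")
    rng_seed = int(seed) % (2**31 - 1)

    if fixed_k is not None:
        if fixed_k > n:
            raise ValueError(f"fixed_k={fixed_k} exceeds sample size {n}")
        km = KMeans(n_clusters=fixed_k, init="k-means++", n_init=10, random_state=rng_seed)
        km.fit(sample)
        return AnchorSet(anchors=km.cluster_centers_, chosen_k=fixed_k, silhouette_by_k={})

    if n < k_max:
        warnings.warn(
            f"sample of {n} points smaller than k_max={k_max}; shrinking sweep",
            stacklevel=2,
        )
        k_max = n
    # silhouette needs at least one point outside its own cluster
    k_max = min(k_max, n - 1, n_distinct)
    k_min = min(k_min, k_max)

    silhouette_by_k: dict[int, float] = {}
    centers_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=rng_seed)
        assignments = km.fit_predict(sample)
        if len(np.unique(assignments)) < 2:
            continue
        silhouette_by_k[k] = float(silhouette_score(sample, assignments, metric="euclidean"))
        centers_by_k[k] = km.cluster_centers_
    if not silhouette_by_k:
        raise ValueError("silhouette sweep produced no valid clustering")
    best = max(silhouette_by_k.values())
    chosen_k = min(k for k, s in silhouette_by_k.items() if s == best)
    return AnchorSet(
        anchors=centers_by_k[chosen_k],
        chosen_k=chosen_k,
        silhouette_by_k=silhouette_by_k,
    )


def nearest_anchor(x: np.ndarray, anchor_set: AnchorSet) -> int:
    """Index of the Euclidean-nearest anchor; ties break to the lowest index."""
    x = np.asarray(x, dtype=float)
    if anchor_set.n_anchors == 0:
        raise ValueError("empty anchor set")
    if x.shape[-1] != anchor_set.anchors.shape[1]:
        raise ValueError("feature dimension mismatch with anchors")
    d2 = np.sum((anchor_set.anchors - x) ** 2, axis=1)
    return int(np.argmin(d2))


def assign_rows(rows: np.ndarray, anchor_set: AnchorSet) -> np.ndarray:
    """Nearest-anchor index for every row (vectorized)."""
    rows = np.asarray(rows, dtype=float)
    d2 = (
        np.sum(rows**2, axis=1)[:, None]
        - 2 * rows @ anchor_set.anchors.T
        + np.sum(anchor_set.anchors**2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


# ---------------------------------------------------------------------------
# fingerprint / profile updates


def update_fingerprint(fp: Fingerprint, matched: int) -> Fingerprint:
    """Absorb one row assignment into the fingerprint (in place; returned)."""
    if not 0 <= matched < len(fp.counts):
        raise IndexError(f"anchor index {matched} out of range")
    fp.counts[matched] += 1
    return fp


def update_profile(profile: ClassProfile, fp: Fingerprint) -> ClassProfile:
    """Fold one fingerprint into the profile's running mean (in place; returned)."""
    if fp.class_k is not None and fp.class_k != profile.class_k:
        raise ValueError(
            f"fingerprint of class {fp.class_k} cannot update a class-{profile.class_k} profile"
        )
    c = profile.n_absorbed * profile.mean_fingerprint + fp.proportions
    profile.n_absorbed += 1
    profile.mean_fingerprint = c / profile.n_absorbed
    return profile


def batch_fingerprint(
    rows: np.ndarray, anchor_set: AnchorSet, entity_id: str = "", class_k: int | None = None
) -> Fingerprint:
    """Whole-entity fingerprint: histogram of nearest-anchor assignments."""
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] == 0:
        raise ValueError("entity has no rows")
    idx = assign_rows(rows, anchor_set)
    counts = np.bincount(idx, minlength=anchor_set.n_anchors)
    return Fingerprint(counts, entity_id=entity_id, class_k=class_k)


def _nearest_profile(profiles: list[ClassProfile], fp_proportions: np.ndarray) -> ClassProfile:
    d2 = [float(np.sum((p.mean_fingerprint - fp_proportions) ** 2)) for p in profiles]
    return profiles[int(np.argmin(d2))]


# ---------------------------------------------------------------------------
# training and prediction


def _init_profiles(
    entities: list[tuple[str, int, np.ndarray]],
    anchor_set: AnchorSet,
    config: MSCConfig,
    rng: np.random.Generator,
) -> tuple[dict[int, list[ClassProfile]], set[str]]:
    """Initialize per-class profiles from a held-out initial sample.

    Returns the profiles and the ids of entities consumed by initialization
    (excluded from the streaming phase). A class with no initial entities
    starts at the uniform histogram with zero weight, so its first absorbed
    fingerprint replaces it outright.
    """
    m = anchor_set.n_anchors
    uniform = np.full(m, 1.0 / m)
    profiles: dict[int, list[ClassProfile]] = {}
    used: set[str] = set()
    by_class: dict[int, list[tuple[str, np.ndarray]]] = {0: [], 1: []}
    for eid, k, rows in entities:
        by_class.setdefault(k, []).append((eid, rows))
    for k, members in sorted(by_class.items()):
        n_init = int(round(config.init_fraction * len(members)))
        picked = []
        if n_init > 0:
            order = rng.permutation(len(members))[:n_init]
            picked = [members[i] for i in sorted(order)]
        fps = [batch_fingerprint(rows, anchor_set, eid, k).proportions for eid, rows in picked]
        used.update(eid for eid, _ in picked)
        R = config.profiles_per_class
        if not fps:
            profiles[k] = [
                ClassProfile(uniform.copy(), 0, class_k=k, profile_index=r) for r in range(R)
            ]
        elif R == 1:
            profiles[k] = [ClassProfile(np.mean(fps, axis=0), len(fps), class_k=k)]
        else:
            F = np.vstack(fps)
            km = KMeans(
                n_clusters=min(R, F.shape[0]),
                init="k-means++",
                n_init=10,
                random_state=int(rng.integers(2**31 - 1)),
            )
            lab = km.fit_predict(F)
            profiles[k] = []
            for r in range(km.n_clusters):
                sel = F[lab == r]
                profiles[k].append(ClassProfile(sel.mean(axis=0), sel.shape[0], class_k=k, profile_index=r))
            for r in range(km.n_clusters, R):
                profiles[k].append(ClassProfile(uniform.copy(), 0, class_k=k, profile_index=r))
    return profiles, used


def train_msc(
    entities: list[tuple[str, int, np.ndarray]],
    anchor_set: AnchorSet,
    config: MSCConfig | None = None,
) -> MSCModel:
    """Train MSC on a stream of labelled entities.

    Parameters
    ----------
    entities : list of (entity_id, class_k, rows)
        ``rows`` is the entity's (T, d) matrix of preprocessed feature
        vectors in temporal order; ``class_k`` in {0, 1} comes from ground
        truth or from an oracle.
    anchor_set : AnchorSet
        Pre-selected anchors (see :func:`select_anchors`).
    config : MSCConfig
        ``per_row`` granularity follows the literal training loop — after
        every row the entity's partial fingerprint updates the nearest
        profile of its own class; ``per_entity`` updates the profile once
        per entity with the finished fingerprint.

    Entities never cross classes: a fingerprint is only ever compared with,
    and only ever updates, profiles of its own class.
    """
    config = config or MSCConfig()
    for eid, k, _rows in entities:
        if k not in (0, 1):
            raise ValueError(f"entity {eid!r} has unseen class label {k}")
    rng = np.random.default_rng(config.seed)
    profiles, used = _init_profiles(entities, anchor_set, config, rng)
    model = MSCModel(anchor_set=anchor_set, profiles=profiles, config=config)

    for eid, k, rows in entities:
        if eid in used:
            model.fingerprints[eid] = batch_fingerprint(rows, anchor_set, eid, k)
            continue
        if config.update_granularity == "per_entity":
            fp = batch_fingerprint(rows, anchor_set, eid, k)
            target = _nearest_profile(profiles[k], fp.proportions)
            update_profile(target, fp)
        else:  # per_row: profile sees every partial fingerprint
            fp = Fingerprint.empty(anchor_set.n_anchors, entity_id=eid, class_k=k)
            idx = assign_rows(rows, anchor_set)
            for m in idx:
                update_fingerprint(fp, int(m))
                target = _nearest_profile(profiles[k], fp.proportions)
                update_profile(target, fp)
        model.fingerprints[eid] = fp
    return model


def predict(model: MSCModel, rows: np.ndarray) -> int:
    """Class of the Euclidean-nearest mature profile to the entity's
    fingerprint.

    Only profiles that have absorbed at least one fingerprint compete (a
    never-updated initialization profile is not a learned class signature);
    if no profile is mature, all are considered. Ties (exactly equal
    distances) resolve to the lower class label.
    """
    fp = batch_fingerprint(rows, model.anchor_set)
    mature_exists = any(
        p.n_absorbed > 0 for plist in model.profiles.values() for p in plist
    )
    best_class, best_d2 = None, np.inf
    for k in sorted(model.profiles):
        for p in model.profiles[k]:
            if mature_exists and p.n_absorbed == 0:
                continue
            d2 = float(np.sum((p.mean_fingerprint - fp.proportions) ** 2))
            if d2 < best_d2:
                best_class, best_d2 = k, d2
    if best_class is None:
        raise ValueError("model has no profiles")
    return int(best_class)


def predict_cohort(model: MSCModel, entities: list[tuple[str, np.ndarray]]) -> np.ndarray:
    return np.array([predict(model, rows) for _eid, rows in entities])


def predict_rows(model: MSCModel, rows: np.ndarray) -> np.ndarray:
    """Per-row convenience wrapper: each hourly row scored as a 1-row entity."""
    rows = np.asarray(rows, dtype=float)
    return np.array([predict(model, rows[t : t + 1]) for t in range(rows.shape[0])])
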
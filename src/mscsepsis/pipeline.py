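"""End-to-end pipeline: simulate → preprocess → shift → train → interpret.

Stages are deterministic given the run seed; every artifact directory gets
a manifest recording the seed, configuration and package version so a run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import __version__
from .psv_io import Cohort, save_cohort
from .preprocess import preprocess_cohort, fit_scaling, impute_record
from .labelshift import build_shift_suite, DEFAULT_SHIFTS
from .msc import MSCConfig, select_anchors, train_msc, predict, predict_rows
from .metrics import UtilityConfig, confusion_metrics, utility_score
from .synthetic import SynthConfig, ThresholdOracleSpec, generate_cohort, make_threshold_oracle


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and its cause."""


def split_cohort(
    cohort: Cohort,
    test_fraction: float = 0.3,
    seed: int = 0,
    classes: np.ndarray | None = None,
    return_indices: bool = False,
):
    """Patient-level, class-stratified train/test split.

    Splitting at the patient level (never by row) prevents within-patient
    leakage between the splits. Classes present with a single patient
    cannot be stratified and raise; a cohort where only one class occurs at
    all falls back to an unstratified split.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    if classes is None:
        classes = cohort.entity_labels()
    classes = np.asarray(classes, dtype=int)
    present, counts = np.unique(classes, return_counts=True)
    if np.any(counts == 1):
        bad = present[counts == 1]
        raise ValueError(f"cannot stratify: class(es) {bad.tolist()} have a single patient")
    stratify = classes if len(present) > 1 else None
    idx = np.arange(len(cohort.records))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=int(seed) % (2**31 - 1),
        stratify=stratify,
    )
    train_idx, test_idx = np.sort(train_idx), np.sort(test_idx)
    if return_indices:
        return train_idx, test_idx
    mk = lambda sel: Cohort(
        records=[cohort.records[i] for i in sel],
        feature_names=list(cohort.feature_names),
        provenance=cohort.provenance,
    )
    return mk(train_idx), mk(test_idx)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    test_fraction: float = 0.3
    synth: SynthConfig = field(default_factory=SynthConfig)
    shifts: tuple[int, ...] = DEFAULT_SHIFTS
    anchor_k: int | None = 10
    msc: MSCConfig = field(default_factory=MSCConfig)
    anchor_sample: int = 4000
    oracle: ThresholdOracleSpec | None = None
    utility: UtilityConfig = field(default_factory=UtilityConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "synth" in kw:
            kw["synth"] = SynthConfig(**kw["synth"])
        if "msc" in kw:
            kw["msc"] = MSCConfig(**kw["msc"])
        if "oracle" in kw and kw["oracle"] is not None:
            kw["oracle"] = ThresholdOracleSpec(**kw["oracle"])
        if "utility" in kw:
            kw["utility"] = UtilityConfig(**kw["utility"])
        if "shifts" in kw:
            kw["shifts"] = tuple(kw["shifts"])
        return cls(**kw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 — re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole pipeline and return the artifact directory.

    Artifacts: the synthetic cohort (.psv), scaling parameters, shifted-label
    tables, trained MSC and hybrid models (JSON), metrics (JSON), the
    feature-attribution report (TSV) and the profile plots (PNG), plus a
    manifest. Any stage failure aborts with the stage name and cause.
    """
    from .interpret import (attribute_features, contrast_profiles,
                            ground_truth_oracle, make_hybrid, plot_profiles)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    cohort = _stage("simulate")(generate_cohort)(
        dataclasses.replace(config.synth, seed=seed)
    )
    _stage("simulate")(save_cohort)(cohort, out / "cohort")

    train_idx, test_idx = _stage("split")(split_cohort)(
        cohort, config.test_fraction, seed, return_indices=True
    )

    @_stage("preprocess")
    def _preprocess():
        imputed = Cohort(
            [impute_record(r) for r in cohort.records], list(cohort.feature_names),
            cohort.provenance,
        )
        train_view = Cohort(
            [imputed.records[i] for i in train_idx], list(cohort.feature_names),
            cohort.provenance,
        )
        params = fit_scaling(train_view)
        scaled, _ = preprocess_cohort(cohort, params=params)
        params.to_json(out / "scaling.json")
        return scaled

    scaled = _preprocess()

    @_stage("shift")
    def _shift():
        suite = build_shift_suite(scaled, config.shifts)
        for ds in suite:
            ds.to_psv(out / f"shifted_c{ds.shift_c}.psv")
        return suite

    _shift()

    @_stage("train-msc")
    def _train():
        train_records = [scaled.records[i] for i in train_idx]
        rows = np.vstack([r.features for r in train_records])
        rng = np.random.default_rng(seed)
        if rows.shape[0] > config.anchor_sample:
            rows = rows[rng.choice(rows.shape[0], config.anchor_sample, replace=False)]
        anchor_set = select_anchors(rows, seed=seed, fixed_k=config.anchor_k)
        entities = [(r.patient_id, int(r.labels.any()), r.features) for r in train_records]
        model = train_msc(entities, anchor_set, dataclasses.replace(config.msc, seed=seed))
        model.to_json(out / "msc_model.json")
        return model

    model = _train()

    @_stage("train-hybrid")
    def _hybrid():
        spec = config.oracle or ThresholdOracleSpec(
            feature_index=config.synth.drivers[0], threshold=4.0
        )
        oracle = make_threshold_oracle(spec)
        hyb = make_hybrid(
            scaled, oracle, dataclasses.replace(config.msc, seed=seed), seed=seed,
            anchor_k=config.anchor_k, anchor_sample=config.anchor_sample,
            test_fraction=config.test_fraction,
        )
        hyb.msc.to_json(out / "hybrid_model.json")
        return hyb

    hybrid = _hybrid()

    @_stage("evaluate")
    def _evaluate():
        test_records = [scaled.records[i] for i in test_idx]
        truth = np.array([int(r.labels.any()) for r in test_records])
        preds = np.array([predict(model, r.features) for r in test_records])
        report = confusion_metrics(preds, truth)
        row_preds = [predict_rows(model, r.features) for r in test_records]
        row_labels = [r.labels for r in test_records]
        try:
            raw, norm = utility_score(row_preds, row_labels, config.utility)
            report.utility_raw, report.utility_normalized = raw, norm
        except ValueError:  # no septic patient landed in the test split
            pass
        payload = {
            "msc_vs_ground_truth": report.as_dict(),
            "hybrid": {
                "oracle": hybrid.oracle_name,
                "fidelity": hybrid.fidelity,
                "accuracy_vs_ground_truth": hybrid.accuracy_vs_ground_truth,
            },
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    metrics_payload = _evaluate()

    @_stage("interpret")
    def _interpret():
        report = attribute_features(model, scaled.feature_names)
        report.to_tsv(out / "attribution.tsv", scaled.feature_names)
        with open(out / "attribution.json", "w") as fh:
            json.dump(
                {
                    "anchor_salience": report.anchor_salience.tolist(),
                    "feature_scores": report.feature_scores.tolist(),
                    "ranked_features": report.ranked_features,
                },
                fh, indent=1,
            )
        plot_profiles(
            [model, hybrid], out / "profiles.png",
            model_names=["ground-truth MSC", f"hybrid ({hybrid.oracle_name})"],
            feature_names=scaled.feature_names,
        )

    _interpret()

    manifest = {
        "package": "mscsepsis",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": {
            "test_fraction": config.test_fraction,
            "shifts": list(config.shifts),
            "anchor_k": config.anchor_k,
            "synth": dataclasses.asdict(config.synth),
            "msc": dataclasses.asdict(config.msc),
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
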
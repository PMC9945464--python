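# mscsepsis

Interpretable sepsis classification and global interpretation of black-box
sepsis early-warning models, built around the **Multi-set Classifier (MSC)**.

Sepsis kills when it is caught late, yet the machine-learning models that
detect it earliest from hourly ICU records (LSTMs, gradient ensembles) are
opaque: they say *when* to alarm but not *what physiology* they alarm on.
This package is for computational researchers and clinical-ML teams who need
a **global** account of what such a model has learned — not per-instance
LIME/SHAP stories — together with the full training and evaluation pipeline
for the hourly-record setting: imputation and rescaling, early-detection
label shifting, the early-warning utility score, and a synthetic ICU cohort
generator so everything is testable without access to protected data.

## The model

Each patient *j* is a multi-set of hourly feature vectors (their stay), not
one point. MSC works in three steps:

1. **Anchors** Q̂ = {q̂₁,…,q̂ₘ}: representative vectors chosen by kmeans++
   clustering of a sample of the preprocessed feature space. The number of
   anchors is picked by a silhouette sweep over k = 2…10 (or fixed, e.g. 10).
2. **Fingerprints** fpⱼ = (p_{j1},…,p_{jm}): the normalized histogram of
   nearest-anchor (Euclidean) assignments over the patient's rows. Updates
   are streaming — when row t matches anchor *i*:
   f = p_{ji}·n_j + 1, n_j ← n_j + 1, p_{ji} = f / n_j —
   implemented over integer counts so the histogram stays exactly normalized.
3. **Class profiles** c_k: the running mean of the fingerprints pooled
   within class k (sepsis k=1, non-sepsis k=0); fingerprints never cross
   classes during training. A new patient is classified by the class of the
   Euclidean-nearest mature profile.

Because profiles are low-dimensional histograms over anchors, and anchors
are points in the clinical feature space, the model is directly readable:
the **profile contrast** c₁ − c₀ says which anchor patterns the sepsis class
over-expresses, and the **anchor-mixture difference**
|Σᵢ c_{1i} q̂ᵢ − Σᵢ c_{0i} q̂ᵢ| pushes that contrast back onto individual
features and ranks them.

**Interpretation mechanism (IM).** Any label source — ground truth or a
black-box model's per-hour predictions — is an *oracle*. Training MSC on an
oracle's labels yields a *hybrid model* whose profiles approximate what the
oracle has learned; its **fidelity** (agreement with the oracle's labels on
held-out patients) measures how much of the black box the surrogate
captures.

Also included: the **label-shift paradigm** (re-pair each row r_t with the
future label l_{t+c}, c ∈ {1, 6, 12} h, so non-temporal models learn early
detection), the **early-warning utility score** (piecewise per-hour rewards
peaking 6 h before onset, normalized so optimal = 1 and silent = 0), the
Wilcoxon rank-sum feature screen, and five-number summary tables.

## Worked example

```python
import numpy as np
import mscsepsis as m

cohort = m.generate_cohort(m.SynthConfig(n_patients=300, d=40, drivers=(0, 1, 2),
                                         delta=1.5, missing_rate=0.2, seed=42))
scaled, params = m.preprocess_cohort(cohort)

train, test = m.split_cohort(scaled, test_fraction=0.3, seed=42)
rows = np.vstack([r.features for r in train])
sub = rows[np.random.default_rng(42).choice(rows.shape[0], 4000, replace=False)]
anchors = m.select_anchors(sub, seed=42, fixed_k=10)
entities = [(r.patient_id, int(r.labels.any()), r.features) for r in train]
model = m.train_msc(entities, anchors, m.MSCConfig(update_granularity="per_entity", seed=42))

preds = np.array([m.predict(model, r.features) for r in test])
rep = m.confusion_metrics(preds, test.entity_labels())
report = m.attribute_features(model, scaled.feature_names)

oracle = m.make_threshold_oracle(m.ThresholdOracleSpec(feature_index=0, threshold=4.5))
hybrid = m.make_hybrid(scaled, oracle, seed=42, anchor_k=10)
```

Output (printing the quantities above):

```
patients: 300  septic: 19
held-out accuracy 0.989  recall 0.833  specificity 1.000
top 5 features: ['F02', 'F00', 'F01', 'F18', 'F34']
anchor salience: [-0.046 -0.076 -0.07  -0.022  0.418  0.008 -0.055 -0.073 -0.011 -0.073]
hybrid fidelity 0.733  accuracy vs truth 0.822
```

Reading this: the synthetic cohort plants a post-onset mean shift of 1.5
scaled units in features F00–F02 of septic patients. The trained MSC
separates held-out patients almost perfectly, its sepsis profile
over-expresses anchor 4 (salience +0.42 — the anchor capturing elevated
driver values), and pushing the profile contrast back to features ranks the
three true drivers at the top. The hybrid trained on a threshold oracle
watching F00 agrees with that oracle on 73% of held-out patients — the
fidelity of the surrogate explanation.

The same pipeline is scriptable end to end:

```sh
msc-interpret simulate --n 300 --seed 42 --out raw/
msc-interpret preprocess --in raw/ --out pre/ --scaling-json scaling.json --fit
msc-interpret shift --in pre/ --c 6 --out shifted_c6.psv
msc-interpret train-msc --in pre/ --anchors 10 --seed 42 --out model.json
msc-interpret interpret --model model.json --features features.txt --top 5 --out attr.tsv
msc-interpret run --out run/ --seed 42        # whole pipeline + manifest
```

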
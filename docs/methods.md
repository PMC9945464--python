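# Methods

## Setting and data model

The package operates on hourly ICU records: one table per patient, ~40
clinical variables per hour, a binary per-hour sepsis label that is
*absorbing* (once positive it stays positive), and very high missingness —
most laboratory values are measured a few times per stay. Internally a
`PatientRecord` keeps three layers per cell: the value, an *observed* mask
(the cell was actually measured), and after imputation a *filled* mask (the
cell was reconstructed from neighbouring measurements). Keeping the
tri-state explicit is what lets 0 serve unambiguously as the missing
sentinel after rescaling without ever confusing it with a measured zero.

## Preprocessing

Imputation fills each feature column by decreasing information content: a
gap bracketed by observations on both sides takes the mean of the nearest
preceding and nearest subsequent observed values (a run of any length gets
that single bracketed mean, not a linear ramp — the simplest reading of
"mean of the preceding and subsequent observations"); a trailing gap
carries the last observation forward; leading gaps and all-missing columns
become 0. Imputation is idempotent and total.

Rescaling maps each feature affinely onto **[1, 6]**, fitted per feature on
*originally observed training cells only* (fill values are excluded from
the min/max so a long carried-forward tail cannot distort the range).
Observed and neighbour-filled cells are transformed and clipped to [1, 6]
(clipping matters only for held-out values outside the training range);
zero-filled cells stay exactly 0. The unusual target range exists precisely
so that 0 can be reserved for "missing": with a [0, 1] range a measured
minimum and a missing cell would collide. Features that are constant or
never observed in training are flagged *degenerate* and map to the midpoint
3.5 rather than to a fake extreme. Fitting on the training split and
applying to test is a deliberate protocol choice; the alternative (global
fit) differs only through clipping at the extremes.

## Label shifting

`shift_labels` re-pairs each hourly row r_t with the future label l_{t+c}.
With absorbing labels this marks the c hours before onset as positive, so a
model without temporal structure learns pre-onset physiology. The suite
default c ∈ {1, 6, 12} hours matches the clinically meaningful horizons
(1 h ≈ detection, 6 h ≈ optimal early detection, 12 h ≈ early window).
End-of-stay handling is the `clamp` policy by default: t+c past the last
hour pairs with the final label, which is the correct future state for an
absorbing process and preserves row counts; `drop` (discard rows with no
future label) is provided for sensitivity analyses. Under clamp on
absorbing sequences shifting composes additively: shift a then b equals
shift a+b.

## The Multi-set Classifier

**Anchors.** kmeans++ (scikit-learn, `n_init=10`, seeded) over a sample of
preprocessed rows; the number of clusters is chosen by sweeping k = 2…10
and keeping the k with the highest mean silhouette coefficient (ties to the
smallest k; the sweep's upper end is capped at sample size − 1, the largest
k for which the silhouette is defined). A `fixed_k` override (10 for the
sepsis benchmark configuration) skips the sweep. A sample in which all
points coincide is rejected as degenerate.

**Fingerprints.** The per-patient histogram over anchors is maintained as
integer assignment counts; proportions are always counts/n. This implements
the streaming update (f = p·n + 1, n ← n+1, p = f/n) for the matched
component while keeping the whole histogram exactly normalized — updating
only the matched proportion, read literally, would break normalization.
Streamed and batch-computed fingerprints are identical by construction and
by test.

**Profiles and training.** One profile per class by default. Profiles are
initialized from a seeded initial sample of entities (default fraction
0.1), averaged per class; those entities are excluded from the streaming
phase, and a class with no initial entities starts at the uniform histogram
with zero absorbed weight so its first real fingerprint replaces it. Two
update granularities are provided: `per_row` (default; after every row the
entity's partial fingerprint updates the Euclidean-nearest profile of its
own class — the literal training loop) and `per_entity` (one update with
the finished fingerprint; statistically cleaner, order-invariant for one
profile per class, and the one used in the large replicate suites for
speed). Fingerprints never cross classes. Prediction compares the entity's
batch fingerprint against *mature* profiles only (profiles that have
absorbed at least one fingerprint); distance ties break to the lower class,
anchor ties to the lower index. All randomness flows from a single integer
seed.

## Interpretation mechanism

An *oracle* is any per-row label source with the same contract as ground
truth. A *hybrid* is an MSC trained on the oracle's labels: entity class 1
iff any oracle row label is positive (the same any-positive aggregation
used for ground truth — the aggregation convention is our choice, as
per-hour black-box predictions do not dictate one). The hybrid reports
**fidelity** (held-out agreement with the oracle) and accuracy against
ground truth; for the identity oracle the two coincide definitionally.

Attribution contrasts the class profiles: salience sᵢ = c₁ᵢ − c₀ᵢ per
anchor (sums to 0 as a difference of normalized histograms), and the
class-conditional anchor mixtures m_k = Σᵢ c_kᵢ q̂ᵢ give per-feature scores
|m₁f − m₀f|. Raw scores are the default because every feature already
shares the [1, 6] scale; `standardize=True` divides by the per-feature
spread of anchor values for settings where anchor variance differs wildly.
Note the mixture difference is a *profile-weighted* contrast — it asks
where the two classes' typical anchor combinations disagree, which is the
quantitative version of reading grouped profile bar charts side by side.

## Evaluation metrics

Confusion metrics follow the standard definitions; zero-denominator ratios
are reported as 0 with an `undefined` flag rather than NaN. The
early-warning utility score transcribes the public challenge evaluation
scheme: per patient-hour piecewise-linear rewards with breakpoints at
onset − 12 h (reward 0, ramping up), onset − 6 h (peak +1), onset + 3 h
(back to 0); unflagged positive hours after the optimum ramp to −2; false
alarms cost −0.05; true negatives 0. Labels follow the convention that the
first positive label *leads* clinical onset by 6 h, so onset is recovered
as first-positive + 6. Normalization is (U − U_silent)/(U_optimal −
U_silent); the optimal sequence flags septic patients from onset − 12 h
(the first rewarded hour) onward and never flags non-septic patients, so
the normalized score is exactly 1 for it and exactly 0 for silence. All
reward parameters live in `UtilityConfig` rather than being hard-coded.

The rank-sum screen applies the two-sided Wilcoxon rank-sum test per
feature to originally observed cells pooled by patient class, at α = 0.05
with *no* multiplicity correction (a screening, not a confirmatory,
analysis). Pooling hourly cells treats them as exchangeable within class;
with per-patient baseline effects the cells are correlated and the test is
anticonservative under the patient-level null — it is used here to confirm
planted signals, not to control error rates. The five-number summary table
includes zero-filled cells, so a minimum of 0 reads as "has missing hours".

## Synthetic cohort generator

Each patient: stay length uniform on 8–60 h; septic with probability
0.073 (the 2,932 / 40,336 septic fraction of the public challenge data);
per-feature values = population mean 3.0 + per-patient Gaussian offset
(sd 0.3) + hourly Gaussian noise (sd 0.5, optional AR(1) correlation),
clipped to [1, 6]; septic patients draw an onset hour uniform on
[4, T−1] and the configured *driver* features shift by +Δ from onset;
labels are 0 before, 1 from onset; missingness is i.i.d. Bernoulli per cell
(default 0.2), applied last as NaN. Everything derives from one seed.

What it emulates: variable-length stays, heavy missingness, absorbing
labels, realistic class imbalance, and a known post-onset signal the
interpretation mechanism should provably recover. What it does not:
physiological dynamics, inter-feature correlation structure, informative
(non-random) missingness, measurement cadence differences between vitals
and labs, or label noise. Passing tests therefore demonstrate the
machinery's correctness and the recoverability of planted effects — not
clinical performance on real ICU data.

## Problem sizes and numerics

The heavy replicate suite runs 20 seeds × 500 patients × 40 features with
3 drivers at Δ = 1.5 and 20% missingness (~25 s total); anchors there use
`fixed_k=10` on a 4,000-row subsample and `per_entity` training, chosen as
the benchmark-faithful configuration that keeps replicate studies cheap.
Normalization of fingerprints/profiles is asserted to 1e-9 (it is exact in
integer arithmetic for fingerprints; profiles accumulate ~1e-16 float
error per update). PSV round-trips format floats with 10 significant
digits (values re-read within 1e-9). Train/test splits are always
patient-level and class-stratified; row-level splitting would leak
within-patient information.

## Known limitations

- `per_row` training is order-dependent by design (the running profile sees
  partial fingerprints); only determinism under a fixed order is guaranteed.
- Fidelity is measured at the patient level; an hourly-resolution fidelity
  would need per-row surrogate predictions (`predict_rows` exists but is
  O(T) nearest-profile queries per patient).
- The rank-sum screen's pooling caveat above.
- Silhouette-based k selection inherits kmeans' bias toward spherical,
  equally sized clusters; heavily imbalanced anchor structure may be
  under-resolved.
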
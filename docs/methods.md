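# Methods

`otogene` prioritizes candidate genes for autosomal dominant nonsyndromic
hearing loss (ADNSHL) from pure-tone audiometry. This note records the
models, the parameters that matter, the synthetic-data assumptions, and
the design decisions that were genuinely open.

## Data model

An audiogram is a partial map from the ten standard audiometric
frequencies {125, 250, 500, 1000, 1500, 2000, 3000, 4000, 6000, 8000} Hz
to air-conduction thresholds in dB HL, plus the patient's age in years.
This is the conventional 10-frequency span including both half-octave
interludes; thresholds are single per-frequency values (better-ear or
pre-averaged), since ear-specific modeling is out of scope. Valid
thresholds lie in [−10, 130] dB HL — the output limits of clinical
audiometers. A patient record is a *bag* of one or more audiograms with an
optional causative-gene label over a fixed 23-gene panel. Eleven panel
symbols (WFS1, ACTG1, COCH, KCNQ4, MYO7A, EYA4, MYO6, TECTA, COL11A2,
GSDME, POU4F3) are the audioprofiling classics; the remaining twelve slots
are filled with further curated dominant hearing-loss genes (TMC1, MYH14,
MYH9, DIAPH1, CCDC50, GRHL2, SLC17A8, P2RX2, CEACAM16, MIR96, TJP2, CRYM)
and are configurable — any 23-symbol panel can be substituted.

## Preprocessing

Missing thresholds are completed by linear interpolation against the
**grid index** (not raw Hz): audiometric frequencies are near-logarithmic,
so index-linear interpolation is the conventional, fully reproducible
choice. Leading/trailing gaps are extrapolated linearly from the two
nearest observed points; filled values are clamped to [−10, 130] dB.
Imputation requires at least three observed thresholds, never alters an
observed value, and is idempotent. Every model consumes the same
11-feature vector: `[age, thr_125, …, thr_8000]`.

Audiogram *shape* is classified from three band means — L (125–500 Hz),
M (1000–2000 Hz), H (3000–8000 Hz) — with a 15 dB criterion: flat if all
pairwise band differences are within 15 dB; else downsloping if
H − L > 15; else upsloping if L − H > 15; else mid-dip if M exceeds both
L and H by more than 15; anything left defaults to flat. The four-class
taxonomy and its 15 dB threshold are declared defaults (band edges and
threshold are configurable), a stand-in for richer clinical shape
vocabularies.

## Audioprofiles and surfaces

A gene's audioprofile is the per-decade mean audiogram of its labeled
cases (bins [0,10), …, [90,100), half-open; ages on an edge join the
upper bin). Audiograms are weighted equally rather than per patient —
patients with repeat visits contribute each visit. Standard deviations are
reported where at least two audiograms contribute.

The audioprofile surface models threshold as a bivariate polynomial in
(age, frequency index), fitted by unweighted ordinary least squares on the
tensor-product basis, default cubic × cubic. Evaluations are clamped to
the audiometer range. The degree is lowered automatically along the age
axis for thin classes whose observation count cannot support 16
coefficients. Underdetermined fits raise with advice to lower the degree.
Fit quality is reported as residual RMSE in dB; by basis nesting it can
never exceed the RMSE of the best constant surface.

The profile distance of an audiogram to a gene is the RMS dB difference
to the profile row of the audiogram's age bin; when that bin is empty the
nearest non-empty bin is used and the result carries a fallback flag.

## Single-instance classifier

For patients with a single audiogram, a partitioned heterogeneous
ensemble: training audiograms are stratified by

* **volume** — a gene is high-volume when its audiogram count reaches the
  median per-gene count;
* **age** — young (< 20), mid (20–59), old (≥ 60); boundary ages join the
  older band;
* **shape** — flat / downsloping / other.

Eleven submodels are bound to strata: three KNN models (k = 5, 15, 31) on
the age strata, six AdaBoost models (100 decision stumps) on the
volume × {flat, downsloping, other} cells, two random forests (200 trees)
on the volume strata. The binding is a documented default — the
partitioning axes are fixed, their wiring to submodels is configurable.
A multinomial logistic regression fuses the concatenated submodel
probability vectors; it is trained on out-of-fold submodel outputs
(internal 5-fold stacking) so the fuser never sees resubstitution
probabilities. An empty or single-class stratum falls back to training on
the full data, with the event recorded on the fitted model.

At prediction time all eleven submodels score every input. The volume
stratum of a new patient is a property of the unknown gene, so per-input
applicability cannot be decided for volume-bound submodels; emitting all
eleven keeps the fuser's input fixed-length, and the partitioning acts
through what each submodel saw in training. Features are z-scored inside
the KNN pipelines (age and dB are on different scales); tree-based
submodels are scale-equivariant and consume raw features.

Singleton classes (one audiogram) are excluded with a warning and recorded
on the model. Output is a probability distribution over the full panel,
with untrained genes at probability zero before renormalization. Fits are
deterministic under the seed and invariant to training-row order (rows are
canonically sorted before fitting).

## Multi-instance classifier

For patients with two or more audiograms: one RBF-SVM per unordered class
pair, trained on per-audiogram feature vectors (z-scored), calibrated by a
Platt sigmoid fitted to cross-fitted decision values (3-fold). Per
audiogram, the 253 pairwise win-probabilities are coupled into a
multiclass distribution with the Hastie–Tibshirani iterative scheme
(`p_i ← p_i · Σ_j r_ij / Σ_j μ_ij`, renormalized; convergence when the
largest update falls below 1e-8, cap 1000 sweeps). The two-class fixed
point reproduces the input probability exactly. Bag aggregation is the
arithmetic mean of the audiograms' coupled distributions — symmetric,
idempotent on duplicated instances, and reducing to the single-instance
coupled output for bags of one. Max and noisy-OR aggregation were
considered and rejected as defaults: the mean is the only choice that is
simultaneously permutation-invariant, duplication-idempotent and smooth in
each instance.

The historical engine this design follows used "modified" SVM probability
outputs; the modification is unpublished, so calibration here is the
standard Platt sigmoid and the question is surfaced as unresolved. A
semisupervised hook exists but is disabled — no unlabeled-data mechanism
is part of the default path.

Routing: bags of size one go to the ensemble, larger bags to the pairwise
model; the route taken is recorded in the report.

## Cluster/embedding atlas

Features are z-scored (scaler fitted on training data — age in years and
thresholds in dB are incommensurate), partitioned into 23 groups by
k-means (k-means++ initialization, 10 restarts, best inertia kept,
tolerance 1e-6), and embedded into three dimensions with UMAP
(n_neighbors 15, min_dist 0.1, fixed seed). Assignments are re-derived as
exact nearest centroids with ties broken toward the lower cluster index.
New patients are placed by the embedding's native out-of-sample transform
rather than by refitting — the dashboard adds one red marker without
recomputing the map. Whether to cluster raw or standardized features was
an open choice; standardized was selected because otherwise age (range
~0–100) is dominated by ten threshold dimensions (range −10–130).

## Confidence flag

For the top-3 genes of a prediction, two concordance scores: the mean
profile distance of the patient's audiograms to the gene's audioprofile
(dB RMS), and the cluster support — the fraction of the patient's assigned
cluster labeled with that gene (averaged over the bag's audiograms). The
flag is **green** iff at least one top-3 gene has profile RMS ≤ τ_rms
(default 15 dB) *and* cluster support ≥ τ_sup (default 0.05); otherwise
**red**. Boundary values count (≤ / ≥), and the rule is monotone:
improving any score can only move red → green. The thresholds are declared
heuristics: clinicians read a few-dB profile agreement as a match, and
15 dB adds headroom for ~10 dB measurement noise; 0.05 asks only that the
gene be non-negligibly present in the local cluster. Both are configurable
arguments, not tuned constants.

## Evaluation

Top-k accuracy is the fraction of patients whose true gene appears among
the k highest-ranked predictions (ties broken by panel order, so top-1 is
a prefix of top-3). Precision and recall use the top-1 gene as the hard
call and are macro-averaged over the classes present in the labels —
macro, because the panel is heavily imbalanced and micro-averaging would
hide tail-class failures; the averaging is configurable. Cross-validation
is at patient level (a patient's audiograms never straddle the
train/test split), stratified by gene, with classes smaller than the fold
count simply occupying fewer folds; each fold trains both engines and
routes every held-out patient by bag size.

## Synthetic cohorts

The generator emulates the structure the system assumes, not any real
dataset. Per gene: a baseline audiogram at age 0 and per-frequency
progression slopes (dB/year), so the expected threshold is
`baseline + slope·age`, clamped. The 23 default profiles cover the
archetypes of the field — low-frequency ascending (WFS1-like),
mid-frequency cookie-bite (TECTA/COL11A2-like), flat progressive
(MYO7A/TMC1-like), high-frequency downsloping (KCNQ4/COCH-like) — with
severities and slopes spread so that at age 40 over 90% of gene pairs
differ by ≥ 8 dB RMS while several clinically realistic near-confusable
pairs remain. Measurement noise is i.i.d. Gaussian per threshold
(default SD 10 dB); real audiometric errors are correlated across
frequency — an accepted simplification, which makes the simulated task
slightly harder at fixed SD than correlated noise of the same magnitude
would. Prevalence is Zipf-like (weight ∝ 1/rank), giving the long-tailed
class imbalance the classifiers must survive; visit counts have support
{1, 2, 3} (probabilities 0.40/0.35/0.25, matching one-to-three audiograms
per patient seen clinically) with 1–3-year spacing; first-visit ages are
uniform on [5, 80]. Missingness deletes thresholds independently at a
given rate but never below three observed per audiogram (the three
highest retention draws are kept, biasing the realized rate down by
< 1% at rate 0.3).

What passing tests on this generator do **not** show: performance on real
audiograms, where noise is correlated, prevalence differs by clinic,
profiles overlap more strongly, and labels can be wrong. The simulator
establishes that the machinery recovers known structure under its own
assumptions — a necessary, not sufficient, condition.

## Problem sizes and numerics

The cross-validated recovery experiments use 1000-patient cohorts
(~1850 audiograms) with 5 folds — large enough for every class to appear
and for the tail classes to hold a handful of patients, the regime the
imbalance checks need. Coupling tolerance 1e-8; surface fits use
`numpy.linalg.lstsq`; k-means tolerance 1e-6 with 10 restarts; all seeds
flow from a single integer per run, and a pipeline rerun under the same
configuration is byte-identical in metrics and payloads.

## Known limitations

* The stratum-to-submodel binding and the shape taxonomy are declared
  defaults, not reconstructions of any historical tool's internals.
* Audioprofiles weight audiograms, not patients; longitudinal patients
  pull the profile toward their trajectory.
* The UMAP out-of-sample transform places new points approximately; a
  refit can move cluster geometry.
* The flag thresholds encode a clinical heuristic, not a calibrated
  decision rule; no claim of sensitivity/specificity on real data is made.
* The semisupervised hook of the bag classifier is intentionally inert.
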
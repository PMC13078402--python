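# otogene

Audiogram-based gene prioritization for autosomal dominant nonsyndromic
hearing loss (ADNSHL).

ADNSHL is genetically heterogeneous — dozens of genes produce clinically
similar hearing loss — but many genes leave a characteristic fingerprint
in the audiogram: *which* frequencies deteriorate, *how fast*, and *from
what age*. `otogene` turns that fingerprint into a ranked list of
candidate genes over a curated 23-gene panel, together with the
interpretive context a clinician needs to decide how much to trust the
ranking.

## What it computes

Given pure-tone audiograms (thresholds in dB HL at up to ten frequencies,
125 Hz–8 kHz, plus age), the package provides:

* **Gene ranking.** Patients with a single audiogram are scored by a
  partitioned heterogeneous ensemble — training data stratified by
  per-gene volume, age band and audiogram shape; 3 KNN + 6 AdaBoost + 2
  random-forest submodels fused by logistic regression on out-of-fold
  stacked probabilities. Patients with two or more audiograms are treated
  as *bags*: one calibrated SVM per class pair, pairwise win-probabilities
  coupled into a multiclass distribution by the Hastie–Tibshirani scheme
  (for the pairwise table *r*, iterate
  `p_i ← p_i · Σ_j r_ij / Σ_j μ_ij` with `μ_ij = p_i/(p_i+p_j)` to the
  minimum-KL fixed point), then averaged over the bag.
* **Audioprofiles.** Per-gene mean audiograms by age decade, and fitted
  audioprofile surfaces `threshold = f(age, frequency)` (tensor-product
  polynomial least squares) showing gene-specific progression in 3-D.
* **Phenotype atlas.** k-means partition of standardized 11-feature
  vectors `[age, thr_125 … thr_8000]` into 23 groups and a 3-D UMAP
  embedding, with out-of-sample placement of a new patient among the
  genetically confirmed cases.
* **Confidence flag.** For the top-3 genes: RMS distance of the patient
  to each gene's audioprofile and the gene's share of the patient's
  cluster. *Green* if at least one candidate is profile-close (≤ 15 dB)
  and cluster-supported (≥ 5%); otherwise *red* — the ranking deserves
  caution. Rankings of this kind put the causative gene in the top 3
  roughly 70–75% of the time, so the flag is the difference between a
  testable hypothesis and a warning.
* **Synthetic cohorts.** A generator with 23 gene-specific progressive
  profiles (baseline + dB/year slopes), Gaussian measurement noise,
  Zipf-like class imbalance, 1–3 visits per patient and controllable
  missingness — every stage of the package is testable without clinical
  data.

## Worked example

```python
from otogene import simulate, default_panel, train_artifacts, predict_record

records = simulate(default_panel(), 200, seed=7)   # synthetic cohort
artifacts = train_artifacts(records, seed=7)       # both engines + atlas + profiles
report = predict_record(artifacts, records[2])     # true gene: ACTG1
print(report.route, report.top3, report.flag)
```

prints

```
single_instance ['ACTG1', 'COCH', 'MYH9'] green
```

and `report.to_dict()` carries the full ranking and concordance:

```
"top3": ["ACTG1", "COCH", "MYH9"],
"concordance": {
  "ACTG1": {"profile_rms_db": 7.548, "cluster_support": 0.1429, ...},
  "COCH":  {"profile_rms_db": 10.542, "cluster_support": 0.0714, ...},
  "MYH9":  {"profile_rms_db": 13.372, "cluster_support": 0.0,    ...}
},
"flag": "green"
```

The generating gene ACTG1 is ranked first with probability 0.34, its
audioprofile sits 7.5 dB RMS from the patient and accounts for 14% of the
patient's cluster — both within the green thresholds, so the prediction
is flagged as trustworthy context for targeted testing.

The same flow is available from the shell:

```bash
otogene simulate --n 500 --seed 17 --missing 0.15 --out synth.csv
otogene train    --input synth.csv --out model.joblib --seed 17
otogene predict  --model model.joblib --input synth.csv --report report.json
otogene evaluate --input synth.csv --cv 5 --seed 17 --out metrics.json
otogene export   --model model.joblib --input synth.csv --outdir payloads/
```

`export` writes the six dashboard payloads (audioprofile curves, surface
grids, gene-count bars, region pie, cluster scatter + composition, age
scatter) as renderer-agnostic JSON.

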
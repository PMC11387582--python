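# Methods

`smacsf` re-implements, as a tested library, the analysis stack of a
CSF-proteomics biomarker study in spinal muscular atrophy (SMA): severity
stratification of naive patients from their baseline (T0) proteome with a
repeated Random-Forest consensus selector, treatment-effect contrasts
between baseline and an on-treatment timepoint (T302), and responder
analyses on per-patient fold changes. Because the original cohort data are
not bundled, every behavioral claim is established on synthetic cohorts
with planted, recorded ground truth.

## The synthetic cohort model

`cohort.generate_cohort` simulates a paired-timepoint, three-subtype cohort
directly on the log2 scale. Each protein has a baseline abundance drawn
uniformly from 20–35 (typical MaxLFQ log2 intensities); each sample adds a
Gaussian shift (sd 0.3 log2-units) emulating loading/acquisition drift, and
each cell adds independent Gaussian noise. Planted structure, all on
disjoint protein index sets by default:

- **Baseline markers** shift monotonically across severity subtypes by
  `baseline_effect` log2-units per adjacent subtype (random sign per
  marker), at both timepoints. Default 9 markers at 1.5 log2-units.
- **Age effects**: a designated subset (default 50 proteins) gains
  `age_slope` (default 0.05 log2-units/year) times centered age. Ages are
  drawn per subtype around medians 2.1 / 7.7 / 15.3 years (sd 3, truncated
  at 0.1), so age is deliberately confounded with severity, as in the
  cohort being emulated.
- **Treatment effects** at T302 only: one shared set (default 20 proteins,
  −1 log2-unit, the direction of the axonogenesis-related down-regulation
  signature) and one set per subtype (default 20 proteins, +1).
- **Responder effects**: a further set shifted only in responder patients
  at T302. Responder fractions default to 11/19, 6/19 and 6/23 per subtype
  (23 of 61 overall); motor scores (CHOP-INTEND for SMA1, HFMSE otherwise)
  are generated so that the score-gain rule reproduces the planted flags
  exactly.
- **Missingness** is missing-completely-at-random dropout (default 10%),
  exported as zeros on the raw scale per LFQ convention. Intensity-dependent
  (left-censored) missingness is not modeled; min-imputation is therefore
  conservative rather than faithful on this generator.

Patient counts default to 19/19/23 and the matrix to 1625 proteins, the
scale of the emulated study. The generator is byte-reproducible from its
seed. What passing tests on these cohorts do **not** show: robustness to
correlated proteins (covariance is diagonal), batch structure, non-Gaussian
tails, or informative missingness. They do establish the logic, the
calibration under exchangeable nulls, and the power behavior of every
stage at realistic effect/noise/sample sizes.

## Preprocessing

Fixed order: log2 → per-sample median-centering → completeness filter →
min-imputation → (per-analysis) z-scaling. Zeros in raw LFQ tables are
missing values, not zero abundances. Median-centering is per sample;
per-protein centering is handled later by the z-scaling stages. The
completeness filter keeps proteins observed in ≥70% of samples of at least
one subtype (threshold configurable; the emulated study does not state
one). Missing values are imputed with the protein's minimum observed value
for model-fitting stages only; the differential tests instead use
pairwise-complete observations.

Scaling for classification is leakage-aware: `fit_scaler` estimates
per-protein mean/sd on the training partition only and `apply_scaler`
applies that frozen state to held-out samples, so no test-set statistic
enters model fitting.

## Repeated Random-Forest consensus selection

The core procedure on T0 samples: stratified 80/20 train/test partition
(per-subtype train count = round(0.8·group size), clipped so each subtype
keeps a test sample), train-only scaling, then a Random Forest with 1000
trees, Gini impurity, at most **3 terminal nodes** per tree (best-first
growth; effectively two splits, matching the observation that subtype
classification is achievable with two-protein combinations), and √p
features per split. Test accuracy is plain proportion correct. Per repeat,
the top 30 proteins by mean decrease in Gini impurity are recorded
(ties broken by protein ID so results are independent of row order). The
procedure repeats with seeds 1..100 and the **consensus set is the strict
intersection** of all 100 top-30 lists; a frequency table reports
near-misses. A `consensus_min_fraction < 1` option relaxes this to
majority-style voting but is not the default rule.

Two forest engines share these semantics. The default drives scikit-learn's
Cython tree builder directly (one splitter/criterion reused across trees,
bootstrap via per-forest RandomState), which is ~10× faster for the many
small forests this procedure fits; the alternative is the stock
`RandomForestClassifier`. The test suite cross-checks the two on planted
cohorts (both reach accuracy 1.0 and rank planted markers on top, with
strongly correlated importance vectors). The engines follow the same model
but different RNG streams, so per-seed outputs are engine-specific;
determinism holds within an engine.

Spearman correlations between consensus-protein abundance and age (BH
adjusted across the set) quantify the residual age confound of any
selected marker.

## Statistics

- **PERMANOVA**: one factor at a time on Euclidean distances, pseudo-F =
  (SS_between/(a−1))/(SS_within/(N−a)) from squared distances, p =
  (#{F_perm ≥ F_obs}+1)/(n_perm+1) over seeded label permutations (default
  999). An `exhaustive=True` mode enumerates all distinct label orderings
  and is tested against a combination-enumeration oracle. Continuous age
  enters as tertiles (PERMANOVA needs groups; the coding is configurable
  and not claimed faithful to any particular study).
- **ANCOVA screen** (baseline): per protein, `abundance ~ subtype + age`
  with a partial (Type-II) F on the subtype term; significance at raw
  p < 0.05 by design of the screen (BH values are still reported).
- **Paired treatment test**: per subtype, two-sided paired t over patients
  with both timepoints; BH within the subtype's protein list; adjusted
  p < 0.05; sign convention: positive = higher at T302. Proteins with <3
  complete pairs are reported with missing p.
- **Responder contrast**: per-patient Δ = T302 − T0, then an unpaired
  two-sided t-test of responders vs non-responders. Welch variance by
  default (robustness at unequal, small class sizes); pooled available.
  Raw p < 0.05; positive = larger change in responders. The fold-change
  convention is T302 minus T0 throughout, so "up" always means up after
  treatment.
- **Responder rule**: CHOP-INTEND gain ≥ 4 (SMA1) or HFMSE gain ≥ 3
  (SMA2/3) between T0 and T302, boundary inclusive; scores outside the
  scale ranges (CHOP 0–64, HFMSE 0–66) are rejected.
- **BH** is the standard step-up procedure (via statsmodels), tested
  against an independent hand-rolled oracle.

## Clustering and PCA

Significant proteins from the paired tests are z-scored per protein
(population sd, so a two-value protein maps to exactly ±1), clustered with
Ward-D2 on Euclidean distances (SciPy's `ward` on observation vectors,
which carries the squared-distance update/`ward.D2` semantics), and cut at
k = 2; the cluster with the higher mean paired difference is labeled "up".
Merge order is verified against a brute-force minimum-ESS-increase oracle.
PCA runs on centered (optionally z-scored) samples; any pair of dimensions
can be exported because group separations often appear beyond the first
two components.

## Over-representation analysis

Gene sets come from a user GMT file. For each set intersected with the
background: fold enrichment = (hits/|query|)/(|set∩background|/|background|)
and upper-tail hypergeometric p = P(X ≥ hits), BH-FDR across tested sets.
The background is the quantified proteome of the analyzed matrix — not a
genome-wide universe — because CSF proteomics detects a strongly biased
protein population; this differs from typical web-service defaults and is
deliberate. Sets with <3 or >500 background members are skipped. ID
mapping to gene symbols is a user-supplied two-column concern; no web
lookups.

## Reproducibility and problem sizes

Every random stage takes an explicit seed; workflows write a JSON manifest
(config, config hash, SHA-256 per artifact) from which a rerun reproduces
all tables byte-identically (asserted in tests). The test suite establishes
the classifier-harness properties at 300 proteins / 60 patients (planted
scenarios) and the consensus-emptiness null at the full study scale of
1625 proteins / 61 patients over 20 replicate cohorts; statistical
calibration checks use 500 proteins and 200 permutation-null simulations.
These sizes were chosen to make the full suite complete in minutes on one
CPU while keeping each check at the sample sizes that matter for its
conclusion.

## Known limitations

- The generator's diagonal covariance understates the feature correlation
  of real CSF proteomes; consensus stability on real data is expected to
  be lower than on planted cohorts.
- Min-imputation plus MCAR dropout is a simplification; no batch
  correction or left-censoring model is provided.
- The strict-intersection rule is sensitive to the number of repeats;
  with fewer repeats the intersection grows. On pure-noise cohorts, chance
  class separation of individual proteins on a fixed dataset can survive
  many lists — emptiness of the consensus holds reliably at top-30 of
  ~1600 proteins but is not guaranteed at top-30 of a few hundred.
- PERMANOVA is marginal per factor; no sequential multi-factor
  partitioning, mixed models, or longitudinal modeling.
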
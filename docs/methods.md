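# Methods

## The modelling pipeline

A QSAR model in this package is not just an estimator: it is the
estimator together with the complete featurization recipe that turned a
raw molecule table into its training matrix. Preparation applies six
steps in a fixed order, and the order matters scientifically:

1. **Row filters.** `CategoryFilter` removes rows by column membership
   (e.g. a source or year). `RepeatsFilter` groups rows with identical
   descriptor vectors: singletons pass, a duplicate group with
   consistent labels (exact for classes, |Δ| ≤ 1e-9 for regression)
   keeps its first row, and a group with conflicting labels is dropped
   entirely — keeping one consistent representative preserves data while
   conflicting duplicates are irreducible label noise.
2. **Descriptor calculation.** Descriptor matrices are pure functions of
   (canonical structure, configuration); each set's columns are prefixed
   with the set name so concatenation never collides.
3. **Train/test split** (see below).
4. **Feature filters**, fitted on training rows only.
5. **Median imputation and standardization**, fitted on training rows
   only and applied to all rows. Missing descriptor values (unmatched
   external-table keys) are filled with the training median of the
   column; the imputation vector is stored so deployment replay is
   exact. Standardization centers and scales by training mean/SD;
   zero-variance columns pass through with scale 1.
6. **Applicability domain** (optional), fitted on the training features;
   test-row in/out flags are recorded and outliers can optionally be
   removed from the test set.

Fitting feature selection and scaling strictly on training rows — and
refitting them *inside every cross-validation fold* — is the package's
defense against information leakage. The test suite asserts this with a
leak-detector feature equal to the target on held-out rows only: its
presence cannot raise the cross-validation score.

## Tasks and targets

Each target property carries a task: `REGRESSION`, `SINGLECLASS` or
`MULTICLASS`. Classification targets may be declared with ascending
thresholds that discretize a continuous column into half-open intervals
`[t_k, t_{k+1})`, boundary to the upper class; the continuous column is
preserved. The model task is derived from the target list: one property
passes through, several of one kind become the `MULTITASK_*` variant,
mixed kinds become `MULTITASK_MIXED`. Multi-task rows missing *some*
targets are retained; their missing labels are imputed at fit time with
the per-task training median and the imputation is recorded in the model
metadata. Median imputation is simple and robust but biases multi-task
models toward central values — scores computed on imputed targets should
be interpreted with care.

## Descriptors

- **Morgan fingerprints**: binary circular-environment bits, default
  radius 3 and 2048 bits — the conventional setting for bioactivity
  modelling and the package default everywhere.
- **Tabular descriptors** serve externally measured values keyed by
  molecule id or SMILES; unmatched rows become missing values handled by
  step 5.
- **Model-as-descriptor** exposes a fitted model's outputs (one column
  per regression task, one per class probability) for stacking.
- **Z-scales**: each amino acid maps to its 3- or 5-dimensional
  principal-property vector from the embedded literature table; `mean`
  mode averages over non-gap positions (invariant to trailing gaps),
  `per_position` mode concatenates per-residue vectors and requires one
  aligned length. The default alignment hook pads with trailing gaps;
  gaps contribute zero vectors. A real multiple-sequence alignment can
  be injected as any callable mapping a sequence dict to an equal-length
  sequence dict.

For PCM, each compound–protein pair row is the concatenation
`[molecular descriptors | protein descriptors of that row's protein]`,
so one model spans multiple targets and two rows sharing a molecule
differ only in the protein block.

## Splits

All splitters are pure functions of (inputs, seed) and return disjoint,
covering, non-empty index sets. Defaults: test fraction 0.2, five CV
folds — common practice. Group-respecting splits never separate rows of
one group:

- **Scaffold split** groups by Bemis–Murcko scaffold with
  stereochemistry stripped; acyclic molecules form singletons. Groups
  are shuffled by seed and fill the test set greedily to the target
  size.
- **Cluster split** runs Taylor–Butina leader clustering on Tanimoto
  distance over the dataset's fingerprints (distance cutoff 0.4, the
  standard default) and packs whole clusters, largest first, into the
  subset furthest below its target size. This deterministic greedy
  packing is a deliberate simplification of globally optimized balanced
  assignment; it trades a little balance for exact reproducibility.
- **PCM split** applies any base split at the molecule level (canonical
  SMILES as the grouping key), then checks each protein's test fraction
  against the global one (tolerance ±0.1), redrawing with an incremented
  seed up to 20 times and keeping the attempt with the smallest maximum
  deviation.
- **Leave-target-out** holds out every row of the named proteins, the
  standard probe of extrapolation to unseen targets.
- **Temporal-per-target** assigns each molecule by its *first*
  occurrence over all proteins, so a compound measured against one
  target in 2010 and another in 2018 is wholly in training for a 2015
  cutoff — avoiding the leakage of "old" compounds re-measured late.

## Feature filters

- **Low variance**: keeps columns with training-set population variance
  (divisor n) strictly above the threshold. The population divisor makes
  thresholds comparable with the p(1−p) variance of binary fingerprint
  bits.
- **High correlation**: scans column pairs in column order and drops the
  later column of any pair with |Pearson r| above the threshold —
  deterministic and order-stable by construction. Zero-variance columns
  are excluded from the scan and left to the variance filter.

## Models and assessment

`SklearnModel` adapts any registered fit/predict estimator; algorithms
are referenced by registry name so hyperparameters round-trip through
JSON. Estimators without native multi-task support are lifted by fitting
one estimator per task (recorded in metadata). Classifier point
predictions are the argmax of class probabilities with ties to the
lowest class index. `MedianBaseline` predicts the per-task training
median everywhere; on any test set with non-zero variance its R² is at
most 0 (0 exactly when test mean and train median coincide), making it
the floor an informative model must clear. Seeds flow from the dataset
to splits and models unless explicitly overridden; a labelled SHA-256
derivation (`derive_seed`) produces stable sub-seeds for folds and
replicas across platforms.

`CrossValAssessor` evaluates on the training portion only, refitting the
feature pipeline per fold as above; one score per fold is returned and
per-row predictions are written to `cv_predictions.tsv` (columns:
`mol_id`, `Fold`, then per target `<name>_Label`, `<name>_Prediction`
and, for classifiers, `<name>_ProbabilityClass_<k>`). `TestSetAssessor`
writes `test_predictions.tsv` in the same schema with the fold label
`Independent Test`. Multi-task scores are computed per task and averaged
for the scalar fold score; benchmarking reports per-task rows. Scores
are always recomputable from the written TSVs.

`GridSearch` evaluates the full Cartesian product of a search space,
aggregates fold scores with a user-chosen reducer (mean default; median
and min available), and breaks ties by product order. The
`HyperparameterOptimization` base class fixes the (search space,
assessor, aggregator) contract so iterative optimizers can be added
without touching callers.

## Applicability domain

Two canonical definitions are implemented behind an open base class:

- **Bounding box**: in-domain iff every feature lies within the training
  [min, max]; monotone under training-set growth.
- **k-NN distance** (k = 5): the threshold is the 95th percentile of
  each training point's mean Euclidean distance to its k nearest
  training neighbours (self excluded). By construction roughly 5% of
  points drawn from the training distribution fall outside; the test
  suite checks 5% ± 3% at n = 1000.

A domain attached to a dataset is fitted during preparation on the
training subset and flags (optionally removes) test outliers; attached
to a model it is fitted on the whole prepared dataset at fit time and
`predict_from_smiles` then emits a per-row `in_domain` flag.

## Serialization and reproducibility

Datasets and models are directories: a `meta.json` written with sorted
keys, UTF-8 and repr-round-trip floats (so save → load → save is
byte-identical), TSV sidecar tables, and per-task estimator payloads
(joblib) referenced from the manifest with SHA-256 content hashes. A
loaded model keeps the original payload bytes and rewrites them verbatim
unless refit. Loading verifies the schema version and the existence of
every manifest file. End-to-end, (raw table, configuration, seed) fully
determine predictions; the CLI acceptance check asserts byte-identical
TSVs across repeated runs.

One known serialization limit: a model-as-descriptor
(`PredictorDescriptor`) inside a saved *dataset* cannot be rebuilt from
its JSON config alone (the stored matrix is preserved, replay on new
molecules is not); use it inside models fitted and saved in one session.

## Benchmarking

`BenchmarkSettings` declares a grid of data sources × descriptor
configurations × preparation variants × models, replicated `n_replicas`
times. The dataset seed is derived from (source, replica) only, so
replicas are paired across preparation variants and models — the
split-difficulty comparison is a paired comparison. Each cell appends
tidy rows (replica, seed, components, target, metric, score) to
`results.tsv` incrementally; completed cells are skipped on resume, and
a failed cell is recorded with its error string without stopping the
run. `compare_split_difficulty` reports per-model means, standard
deviations and paired per-replica deltas; it deliberately performs no
hypothesis test.

## Synthetic fixtures

The generator emulates a small bioactivity study without any external
data. Molecules are enumerated, not sampled: each structural series is a
distinct large ring scaffold (biphenyl, benzanilide, diphenyl ether, …)
decorated at a single position with one of 24 acyclic substituents — a
congeneric series in the medicinal-chemistry sense. One substitution
point on a large shared core keeps within-series Tanimoto similarity
high and between-series similarity low, so scaffold grouping, Butina
clustering and the cluster-vs-random split comparison all operate on
genuine structure. All SMILES are verified to parse at generation time;
generation is a pure function of the spec.

The regression target is
`y = 6.5 + w·(top-variance fingerprint bits) + series offset
(+ protein offset for PCM) + N(0, σ)` with defaults: 10 signal bits,
weights ~ N(0, 1), series offsets spaced 2 log units, protein offsets
spaced 2 log units, σ = 0.3 — series and protein structure dominate the
noise, the regime in which structure-aware validation is genuinely
harder than random splitting. Ground-truth components are returned so
tests can verify exact reconstruction at σ = 0 and signal recovery at
small σ (a ridge model reaches test R² ≥ 0.9 on the 120-molecule,
σ = 0.1 variant). Synthetic proteins are equal-length sequences mutated
from a common seeded ancestor (default length 60, mutation rate 0.1);
PCM fixtures take the full molecule × protein cross (60 × 4 pairs by
default).

What the fixtures do *not* emulate: realistic bioactivity distributions,
assay noise structure, measurement censoring, scaffold diversity beyond
eight templates, sparse compound–protein matrices, or sequence evolution
beyond point substitutions. Passing tests therefore demonstrate the
correctness and reproducibility of the pipeline machinery and the
qualitative split-difficulty ordering — not predictive performance on
real chemistry.

## Numerical choices and degenerate inputs

- R² is 1 − SS_res/SS_tot about the test mean; zero-variance truth is an
  explicit error rather than a silent 0 or NaN.
- Discretization boundaries go to the upper class (half-open intervals).
- Repeats-filter regression tolerance 1e-9; standardizer round-trip
  accurate to 1e-10; CV oracle equivalence asserted to 1e-12.
- Split sizes use round(n × fraction); a fraction yielding an empty
  subset errors immediately.
- All indices are 0-based; subset assignment is stored as a table column
  so it survives serialization.
- Derived seeds are SHA-256 of `"{base}:{label}"` truncated to 31 bits,
  stable across platforms and processes.

## Problem sizes

Test fixtures use 50–120 molecules (up to 240 PCM pairs), 2048-bit
fingerprints, five folds, and 8–10 replicas per benchmark comparison;
the applicability-domain calibration uses 1000 training and 1000
held-out points in 8 dimensions. These sizes keep the whole suite fast
while leaving every statistical check comfortably away from its
decision boundary.
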
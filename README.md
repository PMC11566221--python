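# qsarkit

Modular, serializable QSAR/QSPR and proteochemometric (PCM) modelling
pipelines for cheminformatics and drug discovery.

Quantitative structure–activity/property models map a molecular
structure (a SMILES string) to a property such as a pCHEMBL bioactivity
value. Building such a model is mostly pipeline work: filtering the raw
table, computing descriptors, splitting into training and test sets,
selecting and standardizing features, fitting an estimator, and
assessing it — and then being able to *replay* every one of those steps
on a new molecule at prediction time. qsarkit makes that pipeline a
first-class, serializable object:

- **Datasets** (`QSARDataset`, `PCMDataset`) hold identified molecules,
  target properties with their task semantics (regression, binary or
  multi-class classification, single- or multi-task), train/test
  assignment and the fitted feature-pipeline state.
- **Preparation** runs in a fixed, auditable order: data filters →
  descriptor calculation → train/test split → feature filters (fitted on
  the training set only) → feature standardization (ditto) → optional
  applicability domain. The recipe is stored with the dataset and the
  model.
- **Descriptors**: Morgan (circular) fingerprints, externally supplied
  tables, trained models as descriptors (stacking), and z-scale protein
  descriptors for PCM, where each compound–protein pair is featurized as
  `[molecular block | protein block]`.
- **Splits**: random (optionally stratified), Bemis–Murcko scaffold,
  Taylor–Butina cluster, temporal, manual, bootstrap wrappers, and the
  PCM-aware `PCMSplit`, `LeaveTargetOut` and `TemporalPerTarget`.
- **Models** (`SklearnModel`, `MedianBaseline`, `PCMModel`) wrap
  estimators together with the full featurization recipe; a saved model
  directory predicts from raw SMILES with no other inputs, flags invalid
  SMILES, and reports whether each molecule is inside the applicability
  domain.
- **Assessment**: cross-validation with leakage-safe fold-internal
  refitting of the feature pipeline, test-set assessment, exhaustive
  grid search, and plot-ready summary tables (ROC points, calibration
  bins, per-class one-vs-rest metrics, regression scatter tables). All
  predictions are written as TSV keyed by molecule id.
- **Benchmarking**: a declarative grid of data sources × descriptors ×
  preparation variants × models, repeated over replicas with derived
  seeds, accumulated in a tidy crash-safe results table.
- **Synthetic fixtures** (`qsarkit.synth`): congeneric molecular series
  enumerated from distinct ring scaffolds with a planted linear
  structure–activity relationship, synthetic protein families, and full
  compound–protein crosses — so everything is testable offline.

## Worked example

```python
import qsarkit as qk
from qsarkit.synth import FixtureSpec, make_dataset

ds = make_dataset(FixtureSpec())  # 60 molecules, 3 congeneric series
ds.prepare(descriptor_sets=[qk.MorganFingerprint(radius=3, n_bits=2048)],
           splitter=qk.RandomSplit(test_fraction=0.2),
           feature_filters=[qk.LowVarianceFilter(0.0)],
           standardize=True)
print(f"{len(ds.subset_indices('train'))} train / "
      f"{len(ds.subset_indices('test'))} test molecules, "
      f"{len(ds.feature_names)} features")

model = qk.SklearnModel("knn", "KNeighborsRegressor", {"n_neighbors": 5})
cv = qk.CrossValAssessor(n_folds=5, metric="r2")(model, ds)
print("cross-validation R2 per fold:", [round(s, 3) for s in cv.scores])

model.fit(ds)
test = qk.TestSetAssessor(metric="r2")(model, ds)
print("test-set R2:", round(test.scores[0], 3))

preds = model.predict_from_smiles(["CCOc1ccc(-c2ccccc2)cc1", "not_a_smiles"])
print(preds[["smiles", "valid", "pchembl_Prediction"]])
```

prints

```
48 train / 12 test molecules, 244 features
cross-validation R2 per fold: [0.892, 0.684, 0.483, 0.649, 0.378]
test-set R2: 0.47
                   smiles  valid  pchembl_Prediction
0  CCOc1ccc(-c2ccccc2)cc1   True             5.14771
1            not_a_smiles  False                 NaN
```

The fold scores estimate generalization within the training set; the
test-set R² of 0.47 is the held-out estimate for a 5-nearest-neighbour
regressor on the synthetic pCHEMBL-like target (intercept 6.5, planted
fingerprint-bit weights, per-series offsets, noise σ = 0.3). The last
frame shows deployment: the saved recipe featurizes raw SMILES, invalid
input is flagged rather than raising.

The same workflow is available from the shell via three subcommands:

```bash
qsarkit data    --input mols.csv --smiles-col smiles \
                --target pchembl:REGRESSION --split random \
                --low-variance 0.0 --seed 42 --output run/ds
qsarkit model   --dataset run/ds --algorithm KNeighborsRegressor \
                --params '{"n_neighbors": 5}' --assess both \
                --seed 42 --output run/model
qsarkit predict --model run/model --input mols.csv \
                --smiles-col smiles --output run/preds.tsv
```

Two runs with the same seed produce byte-identical prediction and score
TSVs.

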
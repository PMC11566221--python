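import numpy as np
import pytest

import qsarkit as qk
from qsarkit.synth import FixtureSpec, make_dataset, make_pcm_dataset


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec()


@pytest.fixture()
def dataset():
    """Fresh unprepared 60-molecule regression dataset."""
    return make_dataset(FixtureSpec())


@pytest.fixture(scope="session")
def prepared_dataset():
    """Prepared dataset shared by read-only tests."""
    ds = make_dataset(FixtureSpec())
    ds.prepare(descriptor_sets=[qk.MorganFingerprint()],
               splitter=qk.RandomSplit(0.2),
               feature_filters=[qk.LowVarianceFilter(0.0)],
               standardize=True)
    return ds


@pytest.fixture(scope="session")
def pcm_dataset():
    ds = make_pcm_dataset(FixtureSpec())
    ds.prepare(descriptor_sets=[qk.MorganFingerprint()],
               protein_descriptor_sets=[qk.ZScales(5, "mean")],
               splitter=qk.PCMSplit(qk.RandomSplit(0.2, seed=42)))
    return ds


@pytest.fixture(scope="session")
def fitted_knn(prepared_dataset):
    model = qk.SklearnModel("knn", "KNeighborsRegressor", {"n_neighbors": 3})
    model.fit(prepared_dataset)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
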
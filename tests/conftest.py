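import numpy as np
import pytest

from stackppi import synthetic
from stackppi.io import RunConfig
from stackppi.physchem import PhyschemScaleTable


def fast_config(**overrides) -> RunConfig:
    """A light training configuration for test-scale data.

    Smaller forest/network and grids than the library defaults; the
    architecture (four bases + RBF-SVM meta, out-of-fold meta-data,
    MCC threshold) is unchanged.
    """
    params = dict(
        rf_n_estimators=100,
        ann_hidden_units=25,
        ann_max_iter=150,
        internal_folds=3,
        svm_c_grid=(1.0, 10.0),
        svm_gamma_grid=("scale",),
        meta_cv_folds=3,
        seed=1,
    )
    params.update(overrides)
    return RunConfig(**params)


@pytest.fixture(scope="session")
def scale_table() -> PhyschemScaleTable:
    return PhyschemScaleTable.default()


@pytest.fixture(scope="session")
def toy_fixture():
    return synthetic.build_toy_go_fixture()


@pytest.fixture(scope="session")
def high_signal_dataset():
    """The generator's high-signal study condition: 200 pairs, defaults."""
    return synthetic.generate_dataset(synthetic.SyntheticConfig(seed=1, n_pairs=200))


@pytest.fixture(scope="session")
def small_dataset():
    """A smaller high-signal draw for cheap fitting tests."""
    return synthetic.generate_dataset(
        synthetic.SyntheticConfig(seed=2, n_proteins=40, n_pairs=60)
    )


@pytest.fixture(scope="session")
def small_model(small_dataset):
    from stackppi import stacking

    return stacking.fit(small_dataset, fast_config(seed=2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
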
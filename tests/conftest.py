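import numpy as np
import pytest

import empisim as es


@pytest.fixture(scope="session")
def tooth():
    """The bundled 60-row guinea-pig tooth-growth table."""
    return es.load_tooth_growth()


@pytest.fixture(scope="session")
def tooth_m2(tooth):
    return es.encode_m2(tooth)


@pytest.fixture(scope="session")
def toy_factorial():
    """Small noiseless-ish factorial dataset (n=12) for fast estimation tests."""
    return es.generate_toothlike(es.ToothlikeConfig(reps_per_cell=2, sigma=2.0, seed=7))


@pytest.fixture
def ex_wed_m1():
    return es.ModelSpec("m1", es.DistanceSpec("wed", delta=1), es.SimilaritySpec("ex"))


def make_dataset(x, y, kinds=None):
    """Build a schema-light Dataset from raw numeric covariates."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and len(np.asarray(y).ravel()) > 1:
        x = x.T
    m = x.shape[1]
    schema = es.CovariateSchema(
        names=tuple(f"x{j+1}" for j in range(m)), kinds=("ordinal",) * m
    )
    return es.Dataset(schema, x, np.asarray(y, dtype=float))
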
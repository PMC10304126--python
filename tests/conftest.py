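import numpy as np
import pandas as pd
import pytest

from metstab import METDataset, generate_from_preset


def dataset_from_array(y: np.ndarray, gen=None, env=None) -> METDataset:
    """Build a METDataset from a (g, e, r) yield array."""
    g, e, r = y.shape
    gen = gen or [f"G{i+1:02d}" for i in range(g)]
    env = env or [f"E{i+1:02d}" for i in range(e)]
    idx = pd.MultiIndex.from_product(
        [gen, env, range(1, r + 1)],
        names=["genotype", "environment", "replicate"])
    return METDataset(
        pd.DataFrame({"yield": y.ravel()}, index=idx).reset_index())


@pytest.fixture
def toy222() -> METDataset:
    """Hand-enumerable 2 genotypes x 2 environments x 2 blocks."""
    y = np.array([[[1.0, 2.0], [3.0, 5.0]],
                  [[2.0, 2.0], [7.0, 6.0]]])
    return dataset_from_array(y)


@pytest.fixture
def small_met() -> METDataset:
    """Random balanced 5 x 4 x 3 fixture, fixed seed."""
    rng = np.random.default_rng(42)
    return dataset_from_array(3.0 + rng.normal(0, 1, (5, 4, 3)) ** 2)


@pytest.fixture(scope="session")
def pea_like():
    """The default pea-like synthetic MET at the package default seed."""
    return generate_from_preset("pea-like", seed=0)
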
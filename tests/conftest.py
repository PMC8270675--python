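import numpy as np
import pandas as pd
import pytest

from velcroseq.windows import CountMatrix


@pytest.fixture
def sample_sheet_3v3() -> pd.DataFrame:
    names = [f"WT_{i}" for i in (1, 2, 3)] + [f"hES9S_{i}" for i in (1, 2, 3)]
    return pd.DataFrame({
        "condition": ["WT"] * 3 + ["hES9S"] * 3,
        "replicate": [1, 2, 3, 1, 2, 3],
    }, index=names)


@pytest.fixture
def nb_matrix_factory(sample_sheet_3v3):
    """Random NB count matrices with configurable shape and depth skew."""

    def make(seed: int, n_windows: int = 2000, mean: float = 80.0,
             dispersion: float = 0.1, depths=None) -> CountMatrix:
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(np.log(mean), 0.7, size=n_windows)
        depths = np.ones(6) if depths is None else np.asarray(depths, float)
        counts = {}
        for i, s in enumerate(sample_sheet_3v3.index):
            m = mu * depths[i]
            counts[s] = rng.negative_binomial(1 / dispersion,
                                              1 / (1 + dispersion * m))
        return CountMatrix(pd.DataFrame(counts), sample_sheet_3v3)

    return make


def random_dna(rng: np.random.Generator, length: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.integers(0, 4, size=length)].tobytes().decode()
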
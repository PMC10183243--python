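import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

import symptomnet as sn


@pytest.fixture(scope="session")
def dass_model():
    """Default 3 x 7 synthetic ground truth, fixed seed."""
    return sn.make_truth(seed=1)


@pytest.fixture(scope="session")
def responses_318(dass_model):
    """A study-sized synthetic response matrix (n = 318)."""
    return sn.sample_ordinal(dass_model, 318, seed=2)


@pytest.fixture()
def write_csv(tmp_path):
    """Write a response table (list of dict-rows or array) to a temp CSV."""

    def _write(rows, columns, name="responses.csv"):
        import pandas as pd

        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    return _write


def random_spd_correlation(p, rng, strength=0.5):
    """A well-conditioned random correlation matrix."""
    A = rng.normal(size=(p, p + 3))
    S = A @ A.T / (p + 3) + strength * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
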
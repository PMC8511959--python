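import warnings

import numpy as np
import pytest

from vacalib import LabelSpace

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture
def space2():
    return LabelSpace(["a", "b"])


@pytest.fixture
def space4():
    return LabelSpace(["Pneumonia", "Diarrhea/Dysentery", "Sepsis", "Other"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def mc_se(chains_draws: np.ndarray) -> np.ndarray:
    """Monte-Carlo standard error of the posterior mean via ESS (per component)."""
    import arviz as az

    arr = np.asarray(chains_draws, dtype=float)
    ess = np.asarray(az.ess(az.convert_to_dataset(arr))["x"])
    sd = arr.std(axis=(0, 1), ddof=1)
    return sd / np.sqrt(np.maximum(ess, 1.0))
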
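import numpy as np
import pytest

import moudflow as mf
from moudflow.preprocess import EncodedMatrix


def make_tiny_config(n=1000, seed=0, **overrides):
    """Three settings, two living statuses, no covariates: fast and exact."""
    kw = dict(
        n_admissions=n,
        living_status_probs={"GroupA": 0.6, "GroupB": 0.4},
        setting_shares={"GroupA": (0.5, 0.3, 0.2), "GroupB": (0.2, 0.3, 0.5)},
        setting_rates={"GroupA": (0.7, 0.4, 0.2), "GroupB": (0.55, 0.3, 0.1)},
        settings=("SettingX", "SettingY", "SettingZ"),
        seed=seed,
    )
    kw.update(overrides)
    return mf.GeneratorConfig(**kw)


def make_matrix(values, ordinal=None):
    """Wrap a plain ndarray as an EncodedMatrix for model-level tests."""
    values = np.asarray(values, dtype=np.float64)
    names = [f"F{j}" for j in range(values.shape[1])]
    flags = np.zeros(values.shape[1], dtype=bool) if ordinal is None else np.asarray(ordinal)
    return EncodedMatrix(values, names, flags, {})


@pytest.fixture(scope="session")
def small_config():
    return mf.default_config(n_admissions=8000, seed=101)


@pytest.fixture(scope="session")
def small_table(small_config):
    return mf.generate_admissions(small_config)
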
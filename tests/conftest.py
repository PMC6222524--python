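import numpy as np
import pytest

from sletherm import builtin_dataset, harmonic_mean_temperature


@pytest.fixture(scope="session")
def study():
    """Built-in metoprolol succinate study: (datasets, fusion properties)."""
    return builtin_dataset("metoprolol_succinate")


@pytest.fixture(scope="session")
def datasets(study):
    return study[0]


@pytest.fixture(scope="session")
def datasets_by_solvent(datasets):
    return {ds.solvent_name: ds for ds in datasets}


@pytest.fixture(scope="session")
def fusion(study):
    return study[1]


@pytest.fixture(scope="session")
def t_hm(datasets):
    return harmonic_mean_temperature(np.concatenate([ds.temperatures for ds in datasets]))
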
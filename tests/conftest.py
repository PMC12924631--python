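import pytest

from swinesim.params import HerdConfig, default_sex_params


@pytest.fixture(scope="session")
def gilt():
    return default_sex_params("gilt")


@pytest.fixture(scope="session")
def barrow():
    return default_sex_params("barrow")


@pytest.fixture(scope="session")
def boar():
    return default_sex_params("boar")


@pytest.fixture(scope="session")
def all_params(gilt, barrow, boar):
    return {"gilt": gilt, "barrow": barrow, "boar": boar}


@pytest.fixture
def default_config():
    return HerdConfig()


@pytest.fixture
def small_config():
    return HerdConfig(n_pigs_per_sex=2, n_replications=2, run_days=15, seed=7)
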
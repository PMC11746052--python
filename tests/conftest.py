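import numpy as np
import pytest

from mesocea import ParametricModel, StudyConfig, builtin_config_path, load_config

# Published survival blocks (per population and arm) used across the suite.
TABLE1_MODELS = {
    ("whole", "pembro", "os"): ParametricModel("loglogistic", {"shape": 1.6860, "scale": 17.8960}),
    ("whole", "chemo", "os"): ParametricModel("gamma", {"shape": 1.6860, "rate": 0.0743}),
    ("whole", "pembro", "pfs"): ParametricModel("loglogistic", {"shape": 2.3470, "scale": 7.6780}),
    ("whole", "chemo", "pfs"): ParametricModel("loglogistic", {"shape": 2.6100, "scale": 7.0350}),
    ("nonepi", "pembro", "os"): ParametricModel(
        "gengamma_prentice", {"mu": 2.3140, "sigma": 0.9550, "Q": -0.8350}
    ),
    ("nonepi", "chemo", "os"): ParametricModel("lognormal", {"meanlog": 2.114, "sdlog": 0.9690}),
    ("nonepi", "pembro", "pfs"): ParametricModel(
        "gengamma_prentice", {"mu": 1.6226, "sigma": 0.9186, "Q": -0.9420}
    ),
    ("nonepi", "chemo", "pfs"): ParametricModel("gamma", {"shape": 2.1439, "rate": 0.3955}),
    ("epi", "pembro", "os"): ParametricModel("loglogistic", {"shape": 1.7230, "scale": 19.0840}),
    ("epi", "chemo", "os"): ParametricModel("gamma", {"shape": 1.8344, "rate": 0.0796}),
    ("epi", "pembro", "pfs"): ParametricModel("loglogistic", {"shape": 2.6670, "scale": 7.8090}),
    ("epi", "chemo", "pfs"): ParametricModel("loglogistic", {"shape": 3.1000, "scale": 7.8590}),
}

OS_MODELS = {k: m for k, m in TABLE1_MODELS.items() if k[2] == "os"}


@pytest.fixture(scope="session")
def whole_cfg() -> StudyConfig:
    return load_config(builtin_config_path("whole"))


@pytest.fixture(scope="session")
def nonepi_cfg() -> StudyConfig:
    return load_config(builtin_config_path("non_epithelioid"))


@pytest.fixture(scope="session")
def epi_cfg() -> StudyConfig:
    return load_config(builtin_config_path("epithelioid"))


@pytest.fixture(scope="session")
def all_cfgs(whole_cfg, nonepi_cfg, epi_cfg):
    return {"whole": whole_cfg, "non_epithelioid": nonepi_cfg, "epithelioid": epi_cfg}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
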
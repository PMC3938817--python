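import pytest

from floranet import (
    Formalism,
    SyntheticConfig,
    build_flowering_topology,
    dense_times,
    generate_panel,
    instantiate_model,
    sample_truth_parameters,
)

FORMALISMS = [f.value for f in Formalism]


@pytest.fixture(scope="session")
def topology():
    return build_flowering_topology()


@pytest.fixture(scope="session")
def models(topology):
    return {f.value: instantiate_model(topology, f) for f in Formalism}


@pytest.fixture(scope="session")
def ma_truth():
    return sample_truth_parameters("mass_action", 1)


@pytest.fixture(scope="session")
def ss_truth():
    return sample_truth_parameters("s_system", 1)


@pytest.fixture(scope="session")
def ma_dense_panel(ma_truth):
    cfg = SyntheticConfig(
        formalism="mass_action",
        timepoints=dense_times(),
        genotypes=("col",),
        noise_cv=0.0,
        seed=1,
    )
    return cfg, generate_panel(cfg, ma_truth)[0]


@pytest.fixture(scope="session")
def ss_dense_panel(ss_truth):
    cfg = SyntheticConfig(
        formalism="s_system",
        timepoints=dense_times(),
        genotypes=("col",),
        noise_cv=0.0,
        seed=1,
    )
    return cfg, generate_panel(cfg, ss_truth)[0]
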
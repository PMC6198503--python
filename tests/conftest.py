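import numpy as np
import pytest

from xyyphen.cohort import CohortConfig, ModuleSpec, VariableDef, generate_cohort


def planted_config(seed: int, r_in: float = 0.7, r_out: float = 0.1,
                   n: int = 64, vars_per_module: int = 4) -> CohortConfig:
    """Three planted correlation modules of plain standard-score variables."""
    modules = [
        ModuleSpec(m, tuple(f"{m}{i}" for i in range(vars_per_module)), r_in, r_out)
        for m in ("a", "b", "c")
    ]
    variables = [
        VariableDef(f"{m}{i}", "standard", 100.0, 15.0)
        for m in ("a", "b", "c")
        for i in range(vars_per_module)
    ]
    return CohortConfig(
        n_participants=n, variables=variables, modules=modules,
        asd_loadings={"a0": 1.0}, seed=seed,
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """One strongly modular synthetic cohort shared across tests."""
    table, truth = generate_cohort(planted_config(seed=20_001))
    return table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort drawn under the full default (study-like) configuration."""
    table, truth = generate_cohort(CohortConfig(seed=20_002))
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
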
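import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from beescale.glmm import MCMCSettings, NonConvergenceWarning
from beescale.simulate import GeneratorTruth, generate_specimens

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # short test chains occasionally sit just above the R-hat threshold;
    # the flagging behaviour itself is tested explicitly
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NonConvergenceWarning)
        yield


@pytest.fixture(scope="session")
def small_table() -> pd.DataFrame:
    """2 families x 8 species x 6 specimens -- quick to fit."""
    table, _ = generate_specimens(
        GeneratorTruth(n_groups=2, species_per_group=8,
                       specimens_per_species_sex=3, seed=101)
    )
    return table


@pytest.fixture(scope="session")
def default_table():
    """The default study condition: 40 species x 10 specimens, with echo."""
    return generate_specimens(GeneratorTruth(seed=42))


@pytest.fixture()
def quick_settings() -> MCMCSettings:
    return MCMCSettings(iterations=600, burn_in=300, seed=7)
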
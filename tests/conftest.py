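import pytest
from hypothesis import settings

from groupskew import BirthCostCurve, EconomyParams, lifehistory_presets

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def econ_params() -> EconomyParams:
    return EconomyParams()


@pytest.fixture(scope="session")
def cost_curve() -> BirthCostCurve:
    return BirthCostCurve()


@pytest.fixture(scope="session")
def lh_presets():
    """The three calibrated life-history presets (shared production curve)."""
    return lifehistory_presets()
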
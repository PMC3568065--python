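import pytest
from hypothesis import settings

from nsclc_cea import default_params

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    """The published base case (10-year horizon, no GPAP)."""
    return default_params()


@pytest.fixture()
def short_params(params):
    """Base case truncated to a 12-cycle horizon for brute-force comparisons."""
    from dataclasses import replace

    return replace(params, horizon_years=12 * 21.0 / 365.25)
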
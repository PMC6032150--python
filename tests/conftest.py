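import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from leamts import build_construct_series, classify_panel, lea2_like, lea38_like


@pytest.fixture(scope="session")
def bases():
    return lea2_like(), lea38_like()


@pytest.fixture(scope="session")
def series(bases):
    return build_construct_series(*bases)


@pytest.fixture(scope="session")
def panel(series):
    return classify_panel(series)
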
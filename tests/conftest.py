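import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from erovar.datasets import (  # noqa: E402
    heat_selected_substitutions,
    load_heat_selected_ddg,
    load_tnaa_cds,
    load_variant_catalog,
)
from erovar.seqcore import translate  # noqa: E402


@pytest.fixture(scope="session")
def tnaa_cds():
    return load_tnaa_cds()


@pytest.fixture(scope="session")
def tnaa_protein(tnaa_cds):
    return translate(tnaa_cds)


@pytest.fixture(scope="session")
def catalog():
    return load_variant_catalog()


@pytest.fixture(scope="session")
def selected_subs():
    return heat_selected_substitutions()


@pytest.fixture(scope="session")
def selected_ddg():
    return load_heat_selected_ddg()
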
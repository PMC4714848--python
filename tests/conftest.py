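import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pcw_protein():
    """A generator-default primary-wall protein with its ground truth."""
    from cesakit import synthdata

    template = synthdata.ProteinSpecTemplate(
        wall_class="PCW", ortholog_type="PCW-type", seed=1
    )
    return synthdata.make_cesa_protein(template)


@pytest.fixture(scope="session")
def showcase():
    """The fixed ortholog/paralog demonstration family."""
    from cesakit import synthdata

    return synthdata.showcase_family(seed=42)
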
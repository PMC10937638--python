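import pytest

from cometab.community import build_community
from cometab.pan import build_pan_model
from cometab.synth import (
    SynthConfig,
    community_diet,
    host_diet,
    make_toy_host,
    make_toy_strains,
)


@pytest.fixture(scope="session")
def cfg():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def strains(cfg):
    return make_toy_strains(cfg)


@pytest.fixture(scope="session")
def pans(strains):
    return {sp: build_pan_model(models, sp) for sp, models in strains.items()}


@pytest.fixture(scope="session")
def male_host():
    return make_toy_host("male")


@pytest.fixture(scope="session")
def female_host():
    return make_toy_host("female")


@pytest.fixture(scope="session")
def hdiet():
    return host_diet()


@pytest.fixture(scope="session")
def cdiet(cfg):
    return community_diet(cfg)


@pytest.fixture(scope="session")
def two_species_community(pans):
    """Formate producer (sp01) + serine producer (sp02)."""
    return build_community(
        [pans["sp01"], pans["sp02"]], {"sp01": 0.6, "sp02": 0.4}, sample_id="S1"
    )


@pytest.fixture(scope="session")
def serine_community(pans):
    """Single-species community secreting L-serine but no formate."""
    return build_community([pans["sp02"]], {"sp02": 1.0}, sample_id="Sser")
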
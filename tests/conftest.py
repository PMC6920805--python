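import pytest
from hypothesis import settings

from pgpb_select import GeneratorConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from pgpb_select.records import FunctionalGroup


@pytest.fixture(scope="session")
def small_campaign():
    """Moderate synthetic campaign shared by read-only tests."""
    cfg = GeneratorConfig(
        seed=7,
        n_per_group={g: 60 for g in FunctionalGroup},
        n_elites_per_group=0,
    )
    return generate_dataset(cfg)
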
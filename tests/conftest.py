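import numpy as np
import pytest

from franklin.pipeline import RunConfig, run_demo
from franklin.synthetic_cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with clear latent structure for unit tests."""
    cfg = GeneratorConfig(
        n_beneficiaries=800,
        n_latent_conditions=4,
        vocab_size=60,
        codes_per_condition=8,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_report():
    """Full-pipeline run at the study-condition scale (shared across tests)."""
    return run_demo(RunConfig(seed=0))


@pytest.fixture(scope="session")
def blocked_cohort():
    """Well-separated condition blocks: no noise codes, high emission."""
    cfg = GeneratorConfig(
        n_beneficiaries=4000,
        n_latent_conditions=10,
        vocab_size=120,
        codes_per_condition=12,
        code_emission_prob=0.9,
        noise_code_rate=0.0,
        zero_dx_fraction=0.0,
        seed=11,
    )
    return generate_cohort(cfg)
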
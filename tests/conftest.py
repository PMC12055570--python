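import numpy as np
import pytest

from ureaflux.io import AssayConfig
from ureaflux.simulate import (
    NOISE_FREE,
    PRESETS,
    control_parameters,
    simulate_cohort,
    simulate_true_enrichment,
)


@pytest.fixture(scope="session")
def control_params():
    return control_parameters()


@pytest.fixture(scope="session")
def control_curves(control_params):
    """Noise-free true enrichment curves for the default control subject."""
    return simulate_true_enrichment(control_params, PRESETS["CONTROL"])


@pytest.fixture(scope="session")
def clean_control_cohort():
    """Four identical noise-free control assays (fast pipeline input)."""
    return simulate_cohort(
        4, "CONTROL", noise=NOISE_FREE, inter_subject_cv=0.0, seed=11
    )


@pytest.fixture(scope="session")
def noisy_control_cohort():
    """Small noisy control cohort with inter-subject spread."""
    return simulate_cohort(6, "CONTROL", seed=5)


@pytest.fixture()
def config():
    return AssayConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
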
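import numpy as np
import pytest

import pulselab as pl


@pytest.fixture
def glucose_shift_config():
    """Sampling design of a fast (glucose-type) shift: 15-min intervals."""
    return pl.SimulationConfig(
        n_proteins=600,
        mu_post=0.433,
        sampling_times=tuple(range(15, 121, 15)),
        noise_cv=0.2,
        seed=20_001,
    )


@pytest.fixture
def clean_config():
    """Noise- and censoring-free design for analytic checks."""
    return pl.SimulationConfig(
        n_proteins=50,
        mu_post=0.433,
        sampling_times=tuple(range(15, 121, 15)),
        noise_cv=0.0,
        detection_limit=0.0,
        sample_scale_cv=0.0,
        seed=7,
    )


@pytest.fixture
def dilution_cohort():
    rng = np.random.default_rng(99)
    return pl.make_cohort(600, rng=rng)
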
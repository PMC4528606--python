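import numpy as np
import pytest

from optlens import OPTParams, generate_profile, species_config


@pytest.fixture
def animal_params() -> OPTParams:
    """Consensus young-animal parameter set."""
    return OPTParams(
        gamma_cz=2.375, gamma_gz=5.13, r_p=0.8, delta=0.1, r_peak=1.2
    )


@pytest.fixture
def noiseless_bovine():
    """Fine-grained noiseless bovine-like profile (r_CZ = 4.5 mm)."""
    cfg = species_config("bovine", seed=0, noise="none", bin_width_fraction=0.02)
    return generate_profile(cfg), cfg


@pytest.fixture
def noisy_mouse():
    """Poisson-noise mouse-like profile at the default sampling."""
    cfg = species_config("mouse", seed=7, noise="poisson")
    return generate_profile(cfg), cfg


def random_valid_params(rng: np.random.Generator, with_tz: bool = True) -> OPTParams:
    """Draw a random admissible parameter set (moderate ranges keep the
    dimensionless densities within a numerically comfortable span)."""
    gamma_cz = float(rng.uniform(0.8, 6.0))
    boa = float(rng.uniform(1.0, 3.0))
    r_p = float(rng.uniform(0.4, 0.95))
    if with_tz:
        return OPTParams(
            gamma_cz=gamma_cz,
            gamma_gz=gamma_cz * boa,
            r_p=r_p,
            delta=float(rng.uniform(0.05, 0.5)),
            r_peak=float(rng.uniform(1.05, 1.4)),
        )
    return OPTParams(gamma_cz=gamma_cz, gamma_gz=gamma_cz * boa, r_p=r_p)
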
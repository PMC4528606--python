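"""Synthetic density-profile generator.

Emulates flat-mount cell-density measurements with the structure the
analysis pipeline assumes: a flat central plateau, a rise starting near
R = 0.8, a sharp peak near R = 1.2, a post-peak decline towards the
meridional rows, species-scale absolute densities, and Poisson counting
noise (nuclei are counted per sampling field, so the count in a field of
area A at local density n is Poisson with mean n*A and the recorded density
is count/A).

The species presets share one dimensionless parameter set — beta/alpha =
2.16, gamma_GZ = 5.13, R_p = 0.8, R_peak = 1.2 (the cross-species consensus
values) with delta = 0.1 (no measured value exists; chosen as a plausible
sharp decline and documented as arbitrary) — and differ only in scale
(r_CZ, n0), which is what makes the scaling-collapse behaviour testable.
The human preset instead has a low plateau edge (R_p = 0.5), beta/alpha =
1.0 with gamma_GZ = 2.0, and no post-peak branch: the profile rises
monotonically to its final point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .ageing import GammaAgeRelation
from .exceptions import DomainError, OutOfValidityError
from .model import OPTParams, predict_N, predict_density
from .profiles import DensityProfile, age_in_days

__all__ = [
    "SyntheticConfig",
    "ANIMAL_PARAMS",
    "HUMAN_PARAMS",
    "SPECIES_PRESETS",
    "species_config",
    "generate_profile",
    "generate_species_panel",
    "generate_ageing_series",
]

#: consensus dimensionless parameters shared by the young-animal presets
ANIMAL_PARAMS = OPTParams(
    gamma_cz=5.13 / 2.16,
    gamma_gz=5.13,
    r_p=0.8,
    delta=0.1,
    r_peak=1.2,
)

#: adult-human-like parameters: low plateau edge, beta/alpha ~ 1, no peak
HUMAN_PARAMS = OPTParams(
    gamma_cz=2.0,
    gamma_gz=2.0,
    r_p=0.5,
    delta=None,
    r_peak=None,
)

#: species scale presets: (r_CZ mm, plateau density cells/mm^2).  Plateau
#: densities anchor on measured values where they exist (rabbit 3500,
#: mouse 5300 cells/mm^2); the rat plateau is set so the shared dimensionless
#: peak reproduces the measured 15900 cells/mm^2 rat peak; the human plateau
#: reproduces the measured 8650 cells/mm^2 maximum at the profile end.
_RAT_N0 = 15900.0 / ANIMAL_PARAMS.n_peak
_HUMAN_N0 = 8650.0 / predict_N(1.2, HUMAN_PARAMS)
SPECIES_PRESETS: dict[str, dict] = {
    "mouse": {"r_cz": 1.0, "n0": 5300.0, "params": ANIMAL_PARAMS},
    "rat": {"r_cz": 1.5, "n0": _RAT_N0, "params": ANIMAL_PARAMS},
    "rabbit": {"r_cz": 3.0, "n0": 3500.0, "params": ANIMAL_PARAMS},
    "bovine": {"r_cz": 4.5, "n0": 4500.0, "params": ANIMAL_PARAMS},
    "human": {"r_cz": 4.0, "n0": _HUMAN_N0, "params": HUMAN_PARAMS},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to generate one synthetic profile.

    ``bin_width`` is the radial sampling step (bin centres are at
    ``bin_width/2 + k*bin_width``), ``field_area`` the counting-field area
    per bin (mm^2), sized by default so a plateau bin holds about 200 nuclei.
    ``noise`` is ``"none"`` or ``"poisson"``; the seed is mandatory.
    """

    params: OPTParams
    r_cz: float
    n0: float
    r_max: float
    bin_width: float
    field_area: float
    seed: int
    noise: str = "poisson"
    species: str = "synthetic"
    age: float | None = None
    age_unit: str = "days"

    def __post_init__(self) -> None:
        if not (self.r_cz > 0 and self.n0 > 0):
            raise DomainError("r_cz and n0 must be positive")
        if not self.bin_width > 0:
            raise DomainError("bin_width must be positive")
        if not self.field_area > 0:
            raise DomainError("field_area must be positive")
        if self.noise not in ("none", "poisson"):
            raise DomainError(f"unknown noise model {self.noise!r}")
        if self.params.delta is not None:
            if self.r_max <= self.r_cz * self.params.r_peak:
                raise DomainError(
                    "r_max must extend beyond the density peak "
                    f"({self.r_cz * self.params.r_peak:.3g} mm)"
                )
        elif not self.r_max > self.r_cz:
            raise DomainError("r_max must exceed r_cz")
        if not isinstance(self.seed, (int, np.integer)):
            raise DomainError("an integer seed is mandatory")


def species_config(
    species: str,
    seed: int,
    noise: str = "poisson",
    bin_width_fraction: float = 0.05,
    plateau_counts: float = 200.0,
    r_max_fraction: float | None = None,
) -> SyntheticConfig:
    """Build the preset configuration for one species.

    ``bin_width_fraction`` and ``r_max_fraction`` are in units of r_CZ;
    ``plateau_counts`` sets the expected nuclei per counting field on the
    plateau, which fixes the field area and hence the noise level.
    """
    try:
        preset = SPECIES_PRESETS[species]
    except KeyError:
        raise DomainError(
            f"unknown species {species!r}; presets: {sorted(SPECIES_PRESETS)}"
        ) from None
    params: OPTParams = preset["params"]
    r_cz, n0 = preset["r_cz"], preset["n0"]
    if r_max_fraction is None:
        # profiles end at the meridional rows, where the post-peak decline
        # has reached an intermediate density (N ~ 0.7 with the preset delta)
        r_max_fraction = 1.35 if params.delta is not None else 1.2
    return SyntheticConfig(
        params=params,
        r_cz=r_cz,
        n0=n0,
        r_max=r_max_fraction * r_cz,
        bin_width=bin_width_fraction * r_cz,
        field_area=plateau_counts / n0,
        seed=seed,
        noise=noise,
        species=species,
    )


def generate_profile(config: SyntheticConfig) -> DensityProfile:
    """Generate one profile from a configuration.

    Bin centres carry the exact model density; with Poisson noise the stored
    density is ``count / field_area`` with the count drawn per field.
    Deterministic under a fixed seed.
    """
    c = config
    centres = np.arange(c.bin_width / 2.0, c.r_max, c.bin_width)
    expected = predict_density(centres, c.params, r_cz=c.r_cz, n0=c.n0)
    if c.noise == "poisson":
        rng = np.random.default_rng(c.seed)
        counts = rng.poisson(expected * c.field_area).astype(float)
        densities = counts / c.field_area
        count_arr = counts
        area_arr = np.full_like(centres, c.field_area)
    else:
        densities = expected
        count_arr = None
        area_arr = None
    return DensityProfile(
        r=centres,
        n=densities,
        species=c.species,
        age=c.age,
        age_unit=c.age_unit,
        count=count_arr,
        area=area_arr,
        meta={
            "synthetic": True,
            "seed": c.seed,
            "noise": c.noise,
            "true_params": c.params.to_dict(),
            "true_r_cz": c.r_cz,
            "true_n0": c.n0,
            "field_area": c.field_area,
        },
    )


def generate_species_panel(
    seed: int,
    species: Sequence[str] | None = None,
    noise: str = "poisson",
    **config_kwargs,
) -> dict[str, DensityProfile]:
    """Generate one profile per species preset, with independent substreams
    derived from a single seed."""
    if species is None:
        species = list(SPECIES_PRESETS)
    children = np.random.SeedSequence(seed).spawn(len(species))
    panel = {}
    for name, child in zip(species, children):
        cfg = species_config(
            name, seed=int(child.generate_state(1)[0] % 2**31),
            noise=noise, **config_kwargs,
        )
        panel[name] = generate_profile(cfg)
    return panel


def generate_ageing_series(
    base: SyntheticConfig,
    ages: Sequence[float],
    gamma_age: GammaAgeRelation,
    c: float,
    r_cz_schedule: Callable[[float], float] | Sequence[float],
    seed: int,
    age_unit: str = "days",
) -> list[DensityProfile]:
    """Generate profiles along an ageing trajectory.

    Per age: gamma_GZ from the fitted relation (beta/alpha from the base
    parameters is held constant), r_CZ from the caller-supplied growth
    schedule, and the plateau density from the conservation constant,
    n_CZ = c / r_CZ.  Every output therefore satisfies n_CZ * r_CZ = c.
    """
    if callable(r_cz_schedule):
        r_czs = [float(r_cz_schedule(a)) for a in ages]
    else:
        r_czs = [float(v) for v in r_cz_schedule]
        if len(r_czs) != len(ages):
            raise DomainError("r_cz_schedule length must match ages")
    children = np.random.SeedSequence(seed).spawn(len(list(ages)))
    out = []
    for age, r_cz, child in zip(ages, r_czs, children):
        gamma_gz = gamma_age(age_in_days(age, age_unit))
        if gamma_gz <= 0:
            raise OutOfValidityError(
                f"gamma_GZ(age={age} {age_unit}) = {gamma_gz:.3g} <= 0"
            )
        params = replace(
            base.params,
            gamma_cz=gamma_gz / base.params.beta_over_alpha,
            gamma_gz=gamma_gz,
        )
        n0 = c / r_cz
        cfg = replace(
            base,
            params=params,
            r_cz=r_cz,
            n0=n0,
            r_max=base.r_max / base.r_cz * r_cz,
            bin_width=base.bin_width / base.r_cz * r_cz,
            field_area=base.field_area * base.n0 / n0,
            seed=int(child.generate_state(1)[0] % 2**31),
            age=age,
            age_unit=age_unit,
        )
        out.append(generate_profile(cfg))
    return out
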
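"""Age evolution of the OPT parameters.

Two empirical regularities drive the ageing layer:

* the product of plateau density and CZ radius, ``n_CZ * r_CZ`` (cells/mm),
  stays constant as the lens grows, so plateau density at any age follows
  from eye size;
* the germinative-zone pull-through ratio ``gamma_GZ`` declines steadily
  with adult age (roughly halving, 2.0 -> 1.1, over adulthood in mouse and
  human), while ``beta/alpha`` is held age-invariant.

A linear relation is used for ``gamma_GZ(age)``: the reported anchors
determine a line and nothing in the data constrains a richer form.  Ages are
normalised internally to days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DomainError, OutOfValidityError
from .model import OPTParams, predict_density
from .profiles import DensityProfile, age_in_days

__all__ = [
    "InvariantFit",
    "GammaAgeRelation",
    "AgeingModel",
    "fit_invariant",
    "fit_gamma_age",
    "predict_profile_at_age",
]


@dataclass(frozen=True)
class InvariantFit:
    """The n_CZ * r_CZ conservation constant."""

    c: float  # cells/mm
    cv: float  # sd/mean of the products; 0 (flagged) for a single entry
    n: int
    single_entry: bool = False


@dataclass(frozen=True)
class GammaAgeRelation:
    """Linear decline gamma_GZ = intercept + slope * age (age in days)."""

    intercept: float
    slope: float  # per day
    age_min: float  # days
    age_max: float  # days
    age_unit: str = "days"

    def __call__(self, age_days: float) -> float:
        if not (self.age_min <= age_days <= self.age_max):
            warnings.warn(
                f"age {age_days:.0f} d outside the fitted range "
                f"[{self.age_min:.0f}, {self.age_max:.0f}] d; extrapolating",
                stacklevel=2,
            )
        return self.intercept + self.slope * age_days


@dataclass(frozen=True)
class AgeingModel:
    """Complete ageing layer: conservation constant, gamma_GZ(age) line and
    the age-invariant beta/alpha ratio."""

    c: float  # cells/mm
    gamma_age: GammaAgeRelation
    beta_over_alpha: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise DomainError(f"c must be positive, got {self.c}")
        if not self.beta_over_alpha > 0:
            raise DomainError("beta_over_alpha must be positive")

    def to_dict(self) -> dict:
        g = self.gamma_age
        return {
            "c_cells_per_mm": self.c,
            "gamma_intercept": g.intercept,
            "gamma_slope_per_year": g.slope * 365.25,
            "beta_over_alpha": self.beta_over_alpha,
            "age_range": [g.age_min, g.age_max],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgeingModel":
        lo, hi = d["age_range"]
        return cls(
            c=d["c_cells_per_mm"],
            gamma_age=GammaAgeRelation(
                intercept=d["gamma_intercept"],
                slope=d["gamma_slope_per_year"] / 365.25,
                age_min=lo,
                age_max=hi,
            ),
            beta_over_alpha=d["beta_over_alpha"],
        )


def fit_invariant(
    series: Sequence[tuple[float, float, float]],
) -> InvariantFit:
    """Estimate C = n_CZ * r_CZ from (age, n_CZ, r_CZ) triples.

    C is the mean of the products; cv their coefficient of variation
    (reported as 0 and flagged for a single entry).
    """
    series = list(series)
    if not series:
        raise DomainError("series must contain at least one entry")
    products = []
    for age, n_cz, r_cz in series:
        if not (n_cz > 0 and r_cz > 0):
            raise DomainError(
                f"n_CZ and r_CZ must be positive (age {age}: {n_cz}, {r_cz})"
            )
        products.append(n_cz * r_cz)
    products = np.asarray(products)
    c = float(products.mean())
    single = products.size == 1
    cv = 0.0 if single else float(products.std(ddof=1) / c)
    return InvariantFit(c=c, cv=cv, n=products.size, single_entry=single)


def fit_gamma_age(
    series: Sequence[tuple[float, float]],
    age_unit: str = "days",
) -> GammaAgeRelation:
    """Least-squares line gamma_GZ = a + b * age from (age, gamma_GZ) pairs."""
    series = list(series)
    if len(series) < 2:
        raise DomainError("need at least two (age, gamma_GZ) observations")
    ages = np.asarray([age_in_days(a, age_unit) for a, _ in series])
    gammas = np.asarray([g for _, g in series], dtype=float)
    if np.unique(ages).size < 2:
        raise DomainError("all ages are equal; the age slope is degenerate")
    slope, intercept = np.polyfit(ages, gammas, 1)
    return GammaAgeRelation(
        intercept=float(intercept),
        slope=float(slope),
        age_min=float(ages.min()),
        age_max=float(ages.max()),
        age_unit=age_unit,
    )


def predict_profile_at_age(
    age: float,
    model: AgeingModel,
    r_cz_at_age: float,
    r_p: float,
    r_peak: float | None = None,
    delta: float | None = None,
    age_unit: str = "days",
    n_grid: int = 200,
    r_max: float | None = None,
    species: str = "predicted",
) -> tuple[OPTParams, DensityProfile]:
    """Predict the full dimensional density profile at a given age.

    gamma_GZ comes from the fitted age relation, gamma_CZ from the
    age-invariant beta/alpha, and the plateau density from the conservation
    constant: n_CZ = C / r_cz_at_age (so n_CZ * r_CZ = C exactly for every
    prediction).  The post-peak branch is omitted by default, matching the
    treatment of aged human profiles where the peak/meridional-row boundary
    is not resolvable.
    """
    if not r_cz_at_age > 0:
        raise DomainError(f"r_cz_at_age must be positive, got {r_cz_at_age}")
    age_d = age_in_days(age, age_unit)
    gamma_gz = model.gamma_age(age_d)
    if gamma_gz <= 0:
        raise OutOfValidityError(
            f"gamma_GZ(age) = {gamma_gz:.3g} <= 0 at age {age} {age_unit}; "
            "outside the model's validity range"
        )
    params = OPTParams(
        gamma_cz=gamma_gz / model.beta_over_alpha,
        gamma_gz=gamma_gz,
        r_p=r_p,
        delta=delta,
        r_peak=r_peak,
    )
    n_cz = model.c / r_cz_at_age
    if r_max is None:
        top = r_peak if r_peak is not None else 1.2
        r_max = top * r_cz_at_age
    grid = np.linspace(0.0, r_max, n_grid + 1)[1:]
    densities = predict_density(grid, params, r_cz=r_cz_at_age, n0=n_cz)
    profile = DensityProfile(
        r=grid,
        n=densities,
        species=species,
        age=age,
        age_unit=age_unit,
        meta={"n_cz": n_cz, "r_cz": r_cz_at_age, "c": model.c},
    )
    return params, profile
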
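"""Governing equations of the ordered pull-through (OPT) model.

The lens epithelium is treated as a two-dimensional, axially symmetric cell
population on the flat-mounted capsule.  At quasi-steady state the per-capita
net cell gain (rate ``alpha`` in the distal central zone, ``beta`` in the
germinative zone, both per day) is balanced by a spatially invariant radial
"pull-through" flux with parameter ``k*`` (mm/day) that removes cells into the
lens body at the periphery.  In dimensionless coordinates ``R = r / r_CZ`` and
``N = n / n0`` the balance reads

    dN/dR = N * (gamma * R - 1) / R,

with ``gamma = rate * r_CZ / k*`` taking the value ``gamma_CZ`` between the
plateau edge ``R_p`` and ``R = 1`` and ``gamma_GZ`` between 1 and the density
peak ``R_peak``.  Beyond the peak the decline towards the meridional rows is
modelled as ``dN/dR = -N / delta`` with a single dimensionless gradient
coefficient ``1/delta``.  Solving piecewise with ``N(R_p) = 1`` gives the
closed forms implemented in :func:`predict_N`; :func:`ode_profile_oracle`
integrates the balance numerically and serves as an independent check of the
closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import (
    DegenerateInputError,
    DomainError,
    IntegrationError,
    UnsupportedRegionError,
)

__all__ = [
    "OPTParams",
    "RateParams",
    "predict_N",
    "predict_density",
    "beta_from_index",
    "estimate_k_star",
    "ode_profile_oracle",
]


@dataclass(frozen=True)
class OPTParams:
    """Dimensionless parameters of the OPT density profile.

    Parameters
    ----------
    gamma_cz :
        Ratio of the central-zone net gain rate to pull-through,
        ``alpha * r_CZ / k*`` (> 0).
    gamma_gz :
        Ratio of the germinative-zone net gain rate to pull-through,
        ``beta * r_CZ / k*`` (> 0).
    r_p :
        Plateau edge: largest dimensionless radius at which density is still
        indistinguishable from the central plateau (0 < r_p < 1).
    delta :
        Decline scale of the post-peak (transitional zone / meridional rows)
        branch; ``None`` means the model is truncated at the peak (as for
        human-like monotone profiles).
    r_peak :
        Dimensionless position of the density peak (> 1).  Required whenever
        ``delta`` is given; may be given alone to truncate evaluation.
    """

    gamma_cz: float
    gamma_gz: float
    r_p: float
    delta: float | None = None
    r_peak: float | None = None

    def __post_init__(self) -> None:
        if not (self.gamma_cz > 0 and math.isfinite(self.gamma_cz)):
            raise DomainError(f"gamma_cz must be positive, got {self.gamma_cz}")
        if not (self.gamma_gz > 0 and math.isfinite(self.gamma_gz)):
            raise DomainError(f"gamma_gz must be positive, got {self.gamma_gz}")
        if not (0.0 < self.r_p < 1.0):
            raise DomainError(f"r_p must lie in (0, 1), got {self.r_p}")
        if self.delta is not None:
            if not (self.delta > 0 and math.isfinite(self.delta)):
                raise DomainError(f"delta must be positive, got {self.delta}")
            if self.r_peak is None:
                raise DomainError("r_peak is required when delta is present")
        if self.r_peak is not None and not self.r_peak > 1.0:
            raise DomainError(f"r_peak must exceed 1, got {self.r_peak}")

    @property
    def beta_over_alpha(self) -> float:
        """Ratio of germinative- to central-zone gain rates, gamma_gz/gamma_cz."""
        return self.gamma_gz / self.gamma_cz

    @property
    def n_cz(self) -> float:
        """Dimensionless density at R = 1 (the CZ/GZ boundary)."""
        return self.r_p * math.exp(self.gamma_cz * (1.0 - self.r_p))

    @property
    def n_peak(self) -> float | None:
        """Dimensionless density at the peak, or None without a peak."""
        if self.r_peak is None:
            return None
        return (
            self.n_cz
            * math.exp(self.gamma_gz * (self.r_peak - 1.0))
            / self.r_peak
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OPTParams":
        return cls(
            gamma_cz=d["gamma_cz"],
            gamma_gz=d["gamma_gz"],
            r_p=d["r_p"],
            delta=d.get("delta"),
            r_peak=d.get("r_peak"),
        )


@dataclass(frozen=True)
class RateParams:
    """Dimensional rates and the proliferation inputs they derive from.

    ``alpha`` and ``beta`` are per-capita net cell gain rates (per day),
    ``k_star`` the pull-through parameter (mm/day), ``index`` the proliferation
    (Ki-67) index as a fraction, ``t_hours`` the cell-cycle time and ``r_cz``
    the CZ radius in mm.
    """

    alpha: float | None = None
    beta: float | None = None
    k_star: float | None = None
    index: float | None = None
    t_hours: float | None = None
    r_cz: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "k_star", "index", "r_cz"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be non-negative, got {v}")
        if self.t_hours is not None and not self.t_hours > 0:
            raise DomainError(f"t_hours must be positive, got {self.t_hours}")
        if self.index is not None and self.index > 1:
            raise DomainError(
                f"index is a fraction in [0, 1], got {self.index}"
            )

    @property
    def gamma_gz(self) -> float:
        """Dimensionless beta * r_cz / k_star implied by the stored rates."""
        if None in (self.beta, self.r_cz, self.k_star):
            raise DomainError("beta, r_cz and k_star are all required")
        return self.beta * self.r_cz / self.k_star

    def consistent_with(self, params: OPTParams, rtol: float = 1e-9) -> bool:
        """Check the reconstructed gamma_gz against a dimensionless set."""
        g = self.gamma_gz
        return abs(g - params.gamma_gz) <= rtol * abs(params.gamma_gz)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "k_star": self.k_star,
            "i_index": self.index,
            "t_hours": self.t_hours,
            "r_cz_mm": self.r_cz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateParams":
        return cls(
            alpha=d.get("alpha"),
            beta=d.get("beta"),
            k_star=d.get("k_star"),
            index=d.get("i_index"),
            t_hours=d.get("t_hours"),
            r_cz=d.get("r_cz_mm"),
        )


def predict_N(R, params: OPTParams):
    """Dimensionless density N at dimensionless radius R.

    Piecewise, continuous at every breakpoint:

    * ``R <= r_p``:                N = 1 (central plateau);
    * ``r_p < R <= 1``:            N = (r_p/R) * exp(gamma_cz * (R - r_p));
    * ``1 < R <= r_peak``:         N = N_CZ * (1/R) * exp(gamma_gz * (R - 1));
    * ``R > r_peak`` (delta set):  N = N_peak * exp(-(R - r_peak)/delta).

    Accepts a scalar or array ``R``; returns the same shape.

    Raises
    ------
    DomainError
        For negative radii.
    UnsupportedRegionError
        For radii beyond ``r_peak`` when no ``delta`` is defined.
    """
    R_arr = np.asarray(R, dtype=float)
    if np.any(R_arr < 0):
        raise DomainError("R must be non-negative")
    scalar = R_arr.ndim == 0
    R_arr = np.atleast_1d(R_arr)

    p = params
    out = np.ones_like(R_arr)

    cz = (R_arr > p.r_p) & (R_arr <= 1.0)
    out[cz] = (p.r_p / R_arr[cz]) * np.exp(p.gamma_cz * (R_arr[cz] - p.r_p))

    gz_hi = p.r_peak if p.r_peak is not None else np.inf
    gz = (R_arr > 1.0) & (R_arr <= gz_hi)
    n_cz = p.n_cz
    out[gz] = n_cz * np.exp(p.gamma_gz * (R_arr[gz] - 1.0)) / R_arr[gz]

    tz = R_arr > gz_hi
    if np.any(tz):
        if p.delta is None:
            raise UnsupportedRegionError(
                "R beyond r_peak requested but delta is not defined; "
                "the model is truncated at the peak"
            )
        out[tz] = p.n_peak * np.exp(-(R_arr[tz] - p.r_peak) / p.delta)

    return float(out[0]) if scalar else out


def predict_density(r, params: OPTParams, r_cz: float, n0: float):
    """Dimensional density (cells/mm^2) at radius r (mm).

    Simply ``n0 * predict_N(r / r_cz, params)``; invariant under joint
    rescaling of ``r`` and ``r_cz``.
    """
    if not r_cz > 0:
        raise DomainError(f"r_cz must be positive, got {r_cz}")
    if not n0 > 0:
        raise DomainError(f"n0 must be positive, got {n0}")
    r_arr = np.asarray(r, dtype=float)
    return n0 * predict_N(r_arr / r_cz, params)


def beta_from_index(index: float, t_hours: float) -> float:
    """Per-capita daily net gain rate from a proliferation index.

    With a cell-cycle time of ``t_hours`` hours, a fraction ``index`` of cells
    in cycle completes 24/t_hours of a division per day, so (assuming minimal
    apoptosis) ``beta = 24 * index / t_hours`` per capita per day.  E.g.
    index 0.005 (0.5%) with a 40 h cycle gives 0.003/day.
    """
    if not t_hours > 0:
        raise DomainError(f"t_hours must be positive, got {t_hours}")
    if not (0.0 <= index <= 1.0):
        raise DomainError(f"index must be a fraction in [0, 1], got {index}")
    return 24.0 * index / t_hours


def estimate_k_star(
    gamma_gz: float, index: float, t_hours: float, r_cz: float
) -> float:
    """Pull-through parameter k* (mm/day) from gamma_gz and proliferation data.

    Inverts ``gamma_gz = beta * r_cz / k*`` with beta from
    :func:`beta_from_index`.
    """
    if not gamma_gz > 0:
        raise DomainError(f"gamma_gz must be positive, got {gamma_gz}")
    if not r_cz > 0:
        raise DomainError(f"r_cz must be positive, got {r_cz}")
    if index == 0:
        raise DegenerateInputError(
            "index = 0 leaves k* unidentifiable (beta = 0)"
        )
    beta = beta_from_index(index, t_hours)
    return beta * r_cz / gamma_gz


def _integrate_segment(rhs, r0, r1, y0, t_eval, rtol, atol):
    sol = solve_ivp(
        rhs,
        (r0, r1),
        [y0],
        method="DOP853",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed on [{r0}, {r1}]: {sol.message}"
        )
    return sol


def ode_profile_oracle(
    params: OPTParams,
    R_grid: Sequence[float],
    rtol: float = 1e-11,
    atol: float = 1e-12,
) -> np.ndarray:
    """Numerically integrate the population balance on a radius grid.

    Integrates ``dN/dR = N (gamma R - 1)/R`` with the zone-appropriate gamma
    (and ``dN/dR = -N/delta`` past the peak) from ``N(r_p) = 1``, entirely
    independently of the closed forms in :func:`predict_N`.  Intended as a
    verification oracle, not as the production evaluation path.
    """
    grid = np.asarray(R_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise DomainError("R_grid must be a non-empty 1-d sequence")
    if np.any(np.diff(grid) <= 0):
        raise DomainError("R_grid must be strictly increasing")
    if grid[0] < 0:
        raise DomainError("R_grid must be non-negative")

    p = params
    gz_hi = p.r_peak if p.r_peak is not None else np.inf
    if p.delta is None and np.any(grid > gz_hi):
        raise UnsupportedRegionError(
            "R_grid extends beyond r_peak but delta is not defined"
        )

    out = np.empty_like(grid)
    out[grid <= p.r_p] = 1.0

    r_max = float(grid[-1])
    segments = [
        (p.r_p, min(1.0, r_max), lambda R, y, g=p.gamma_cz: y * (g * R - 1.0) / R),
    ]
    if r_max > 1.0:
        segments.append(
            (
                1.0,
                min(gz_hi, r_max),
                lambda R, y, g=p.gamma_gz: y * (g * R - 1.0) / R,
            )
        )
    if r_max > gz_hi:
        segments.append(
            (gz_hi, r_max, lambda R, y, d=p.delta: -y / d)
        )

    y = 1.0
    for r0, r1, rhs in segments:
        if r1 <= r0:
            continue
        inside = (grid > r0) & (grid <= r1)
        t_eval = np.unique(np.concatenate([grid[inside], [r1]]))
        sol = _integrate_segment(rhs, r0, r1, y, t_eval, rtol, atol)
        values = dict(zip(sol.t, sol.y[0]))
        out[inside] = [values[t] for t in grid[inside]]
        y = sol.y[0][-1]
    return out
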
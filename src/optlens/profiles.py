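"""Data containers for dimensional and dimensionless density profiles."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = ["DensityProfile", "NormalizedProfile"]

#: factors converting an age unit to days
AGE_UNIT_DAYS = {
    "days": 1.0,
    "weeks": 7.0,
    "months": 365.25 / 12.0,
    "years": 365.25,
}


def age_in_days(age: float, unit: str) -> float:
    try:
        return age * AGE_UNIT_DAYS[unit]
    except KeyError:
        raise DomainError(
            f"unknown age unit {unit!r}; expected one of {sorted(AGE_UNIT_DAYS)}"
        ) from None


@dataclass
class DensityProfile:
    """Radial cell-density measurements from a flat-mounted epithelium.

    ``r`` (mm, strictly increasing from the anterior pole) and ``n``
    (cells/mm^2) are parallel arrays.  When densities come from counting
    nuclei per sampling field, ``count`` and ``area`` (mm^2 per field) may be
    stored; they must satisfy ``n = count / area``.
    """

    r: np.ndarray
    n: np.ndarray
    species: str = "unknown"
    age: float | None = None
    age_unit: str = "days"
    count: np.ndarray | None = None
    area: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.r.shape != self.n.shape or self.r.ndim != 1:
            raise DomainError("r and n must be 1-d arrays of equal length")
        if self.r.size and self.r[0] < 0:
            raise DomainError("radii must be non-negative")
        if np.any(np.diff(self.r) <= 0):
            raise DomainError("radii must be strictly increasing")
        if np.any(self.n < 0):
            raise DomainError("densities must be non-negative")
        if self.count is not None:
            self.count = np.asarray(self.count, dtype=float)
        if self.area is not None:
            self.area = np.asarray(self.area, dtype=float)
        if self.count is not None and self.area is not None:
            implied = self.count / self.area
            scale = np.maximum(np.abs(self.n), 1.0)
            if np.any(np.abs(implied - self.n) > 1e-9 * scale):
                raise DomainError("n must equal count/area where both are given")

    def __len__(self) -> int:
        return self.r.size

    @property
    def age_days(self) -> float | None:
        if self.age is None:
            return None
        return age_in_days(self.age, self.age_unit)

    def to_frame(self) -> pd.DataFrame:
        data = {"r_mm": self.r, "density_per_mm2": self.n}
        if self.count is not None:
            data["count"] = self.count
        if self.area is not None:
            data["area_mm2"] = self.area
        return pd.DataFrame(data)

    def scaled(self, space: float = 1.0, density: float = 1.0) -> "DensityProfile":
        """Return a copy with radii scaled by ``space`` and densities by
        ``density`` (counts/areas dropped: they no longer correspond)."""
        if space <= 0 or density <= 0:
            raise DomainError("scale factors must be positive")
        return replace(
            self,
            r=self.r * space,
            n=self.n * density,
            count=None,
            area=None,
        )


@dataclass
class NormalizedProfile:
    """Dimensionless (R, N) profile plus the constants that produced it.

    ``R = r / r_cz`` and ``N = n / n0``; ``r_p`` is the detected plateau edge
    and ``baseline_sd`` the residual scatter (cells/mm^2) around the plateau
    baseline.  ``count``/``area`` are carried over from the source profile
    when available so that counting-noise weights remain computable.
    """

    R: np.ndarray
    N: np.ndarray
    r_cz: float
    n0: float
    r_p: float
    baseline_sd: float = 0.0
    count: np.ndarray | None = None
    area: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.R.shape != self.N.shape or self.R.ndim != 1:
            raise DomainError("R and N must be 1-d arrays of equal length")
        if not self.r_cz > 0:
            raise DomainError(f"r_cz must be positive, got {self.r_cz}")
        if not self.n0 > 0:
            raise DomainError(f"n0 must be positive, got {self.n0}")
        if not (0.0 < self.r_p < 1.0):
            raise DomainError(f"r_p must lie in (0, 1), got {self.r_p}")

    def __len__(self) -> int:
        return self.R.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"R": self.R, "N": self.N})

    def constants(self) -> dict[str, float]:
        return {
            "r_cz_mm": float(self.r_cz),
            "n0": float(self.n0),
            "r_p": float(self.r_p),
            "baseline_sd": float(self.baseline_sd),
        }

    def redimensionalize(self, **meta) -> DensityProfile:
        """Invert the normalization (exact up to floating point)."""
        return DensityProfile(
            r=self.R * self.r_cz,
            n=self.N * self.n0,
            count=self.count,
            area=self.area,
            **meta,
        )
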
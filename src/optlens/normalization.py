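"""Dimensionless normalization of radial density profiles.

The dimensional profile n(r) is reduced to dimensionless coordinates by three
estimates made from the data alone:

* ``n0`` — the plateau (central-zone) density, the level of a least-squares
  line fitted over the flat central region;
* ``r_cz`` — the CZ/GZ boundary radius, defined geometrically as the
  intersection of that baseline with the tangent to the rising flank at the
  level mid-way between baseline and peak (the "two-line" construction);
* ``R_p`` — the largest dimensionless radius at which the (smoothed) density
  is still indistinguishable from the plateau.

These geometric estimates are deliberately model-free.  They carry a small,
structural bias when applied to sampled curves (the mid-level tangent of a
convex flank intersects the baseline slightly inside the true boundary), so
downstream fitting offers a refinement step that re-estimates the constants
jointly with the model parameters; the functions here provide the initial
values and the model-independent description of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np

from .exceptions import (
    DomainError,
    FlatProfileError,
    GeometryError,
    InsufficientDataError,
)
from .profiles import DensityProfile, NormalizedProfile

__all__ = [
    "Baseline",
    "CollapseComparison",
    "estimate_baseline",
    "locate_r_cz",
    "locate_R_p",
    "to_dimensionless",
    "normalize_profile",
    "collapse_compare",
]


@dataclass(frozen=True)
class Baseline:
    """Plateau baseline: a fitted line n = intercept + slope * r.

    ``n0`` is the level at the centroid of the plateau samples (equal to
    their mean), ``sd`` the residual standard deviation and ``extent`` the
    outermost radius still included in the plateau fit.
    """

    n0: float
    intercept: float
    slope: float
    sd: float
    extent: float
    n_points: int

    def level_at(self, r) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(r, dtype=float)


def _line_fit(r: np.ndarray, n: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(r, n, 1)
    resid = n - (intercept + slope * r)
    ddof = 2 if r.size > 2 else 0
    sd = float(np.std(resid, ddof=ddof)) if r.size > ddof else 0.0
    return float(intercept), float(slope), sd


def estimate_baseline(
    profile: DensityProfile,
    plateau_fraction: float = 0.5,
    min_points: int = 5,
) -> Baseline:
    """Fit the central-zone baseline.

    The candidate plateau is taken as all samples at radii below
    ``plateau_fraction`` of the peak position; a line is fitted and the fit
    repeated once after discarding points more than 2 residual SDs above it
    (guarding against the flank leaking into the window).
    """
    r, n = profile.r, profile.n
    if len(profile) < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} samples, got {len(profile)}"
        )
    # last index attaining the maximum: for a perfectly flat profile the
    # "peak" is then the outermost sample and the whole profile is plateau
    peak_pos = r[len(n) - 1 - int(np.argmax(n[::-1]))]
    if peak_pos <= 0:
        raise FlatProfileError("density peak sits at the pole; no plateau")
    mask = r < plateau_fraction * peak_pos
    if int(mask.sum()) < min_points:
        raise InsufficientDataError(
            f"only {int(mask.sum())} samples inside the candidate plateau "
            f"(r < {plateau_fraction * peak_pos:.3g} mm); need {min_points}"
        )
    intercept, slope, sd = _line_fit(r[mask], n[mask])
    keep = mask & (n <= intercept + slope * r + 2.0 * sd)
    if int(keep.sum()) >= min_points:
        intercept, slope, sd = _line_fit(r[keep], n[keep])
        mask = keep
    return Baseline(
        n0=float(np.mean(n[mask])),
        intercept=intercept,
        slope=slope,
        sd=sd,
        extent=float(r[mask].max()),
        n_points=int(mask.sum()),
    )


def locate_r_cz(
    profile: DensityProfile,
    baseline: Baseline,
    tangent_window: int = 5,
) -> float:
    """Two-line intercept estimate of the CZ/GZ boundary radius (mm).

    Line 1 is the fitted baseline.  Line 2 is a least-squares tangent over
    ``tangent_window`` samples centred on the rising flank's crossing of the
    level mid-way between baseline and peak (the last such crossing before
    the global peak, which is robust to counting noise).  The peak is the
    maximum density; for monotone, human-like profiles this is the final
    sample.  Their intersection radius is r_cz.
    """
    r, n = profile.r, profile.n
    peak_idx = int(np.argmax(n))
    peak = n[peak_idx]
    if peak <= baseline.n0 * (1.0 + 1e-12) + 3.0 * baseline.sd:
        raise FlatProfileError(
            "no rise above baseline + 3 SD; two-line construction undefined"
        )
    mid = 0.5 * (baseline.n0 + peak)

    crossings = [
        i
        for i in range(peak_idx)
        if n[i] <= mid < n[i + 1]
    ]
    if not crossings:
        raise GeometryError("mid-level crossing not bracketed on the rising flank")
    c = crossings[-1]

    half = tangent_window // 2
    lo = max(0, c - half + 1)
    hi = min(len(profile), lo + tangent_window)
    lo = max(0, hi - tangent_window)
    intercept2, slope2, _ = _line_fit(r[lo:hi], n[lo:hi])
    if slope2 <= baseline.slope:
        raise GeometryError(
            "flank tangent is not steeper than the baseline; no intersection"
        )
    r_cz = (baseline.intercept - intercept2) / (slope2 - baseline.slope)
    if not (0.0 < r_cz <= r[-1] * 1.5):
        raise GeometryError(f"two-line intersection at implausible r = {r_cz:.3g}")
    return float(r_cz)


def locate_R_p(
    profile: DensityProfile,
    baseline: Baseline,
    r_cz: float,
    smooth_window: int = 5,
    band_sds: float = 2.0,
    min_band_fraction: float = 0.01,
) -> float:
    """Plateau edge R_p: the largest R at which density is still flat.

    The profile is smoothed with a centred moving average (window
    ``smooth_window``) so counting noise does not trigger spurious
    departures; the departure point is where the smoothed density first
    leaves ``baseline +/- band``, with ``band`` the larger of
    ``band_sds * baseline_sd`` and ``min_band_fraction * n0`` (the floor
    keeps the test meaningful for noiseless data, where the residual SD is
    zero).  The crossing radius is linearly interpolated and only radii
    below r_cz are scanned, so R_p < 1 by construction.
    """
    if not r_cz > 0:
        raise DomainError(f"r_cz must be positive, got {r_cz}")
    r, n = profile.r, profile.n
    kernel = np.ones(smooth_window) / smooth_window
    # centred moving average with shrinking windows at the edges
    smoothed = np.convolve(n, kernel, mode="same")
    norm = np.convolve(np.ones_like(n), kernel, mode="same")
    smoothed = smoothed / norm

    # deviation from the plateau *level*: the fitted baseline slope is kept
    # for the two-line intercept but would mask a slow early rise here
    deviation = np.abs(smoothed - baseline.n0)
    band = max(band_sds * baseline.sd, min_band_fraction * baseline.n0)

    scan = np.flatnonzero(r < r_cz)
    if scan.size == 0:
        raise GeometryError("no samples inside r_cz")
    exceed = [i for i in scan if deviation[i] > band]
    if not exceed:
        warnings.warn(
            "no departure from the plateau detected inside r_cz; "
            "R_p set to the last sample before r_cz",
            stacklevel=2,
        )
        return float(min(r[scan[-1]] / r_cz, 0.99))
    j = exceed[0]
    if j == 0:
        warnings.warn(
            "plateau departure detected at the first sample; "
            "baseline may be unreliable",
            stacklevel=2,
        )
        return float(min(r[0] / r_cz, 0.99))
    # interpolate the crossing of |deviation| = band between j-1 and j
    d0, d1 = deviation[j - 1], deviation[j]
    frac = 0.0 if d1 == d0 else (band - d0) / (d1 - d0)
    frac = float(np.clip(frac, 0.0, 1.0))
    r_p = r[j - 1] + frac * (r[j] - r[j - 1])
    return float(min(r_p / r_cz, 0.99))


def to_dimensionless(
    profile: DensityProfile,
    r_cz: float,
    n0: float,
    r_p: float,
    baseline_sd: float = 0.0,
    provenance: dict[str, Any] | None = None,
) -> NormalizedProfile:
    """Pointwise transform to (R, N) = (r/r_cz, n/n0)."""
    if not r_cz > 0:
        raise DomainError(f"r_cz must be positive, got {r_cz}")
    if not n0 > 0:
        raise DomainError(f"n0 must be positive, got {n0}")
    prov = {
        "species": profile.species,
        "age": profile.age,
        "age_unit": profile.age_unit,
    }
    if provenance:
        prov.update(provenance)
    return NormalizedProfile(
        R=profile.r / r_cz,
        N=profile.n / n0,
        r_cz=float(r_cz),
        n0=float(n0),
        r_p=float(r_p),
        baseline_sd=float(baseline_sd),
        count=None if profile.count is None else profile.count.copy(),
        area=None if profile.area is None else profile.area.copy(),
        provenance=prov,
    )


@dataclass(frozen=True)
class CollapseComparison:
    """Pointwise comparison of two collapsed (dimensionless) profiles.

    ``dN`` is the difference at matched sampling stations, ``se`` the
    combined noise standard error of that difference, and ``z = |dN|/se``.
    """

    dN: np.ndarray
    se: np.ndarray
    z: np.ndarray

    @property
    def max_z(self) -> float:
        return float(self.z.max())

    @property
    def max_abs_dN(self) -> float:
        return float(np.abs(self.dN).max())


def _station_se(nprof: NormalizedProfile, k: int) -> np.ndarray:
    """Noise SE of N per station: Poisson counting error plus the propagated
    uncertainty of the plateau level n0."""
    if nprof.count is not None and nprof.area is not None:
        se_pt = np.sqrt(np.maximum(nprof.count[:k], 1.0)) / (
            nprof.area[:k] * nprof.n0
        )
    else:
        se_pt = np.zeros(k)
    plateau = int(np.sum(nprof.R < nprof.r_p))
    rel_se_n0 = (nprof.baseline_sd / nprof.n0) / max(np.sqrt(plateau), 1.0)
    return np.sqrt(se_pt**2 + (nprof.N[:k] * rel_se_n0) ** 2)


def collapse_compare(
    a: NormalizedProfile, b: NormalizedProfile
) -> CollapseComparison:
    """Quantify how well two normalized profiles collapse onto one curve.

    Assumes the two source profiles were sampled at matched dimensionless
    stations (radial bins proportional to each lens's r_CZ, as the
    flat-mount protocol and the synthetic generator both arrange), so the
    difference is taken station by station with no interpolation — the
    sharp density peak makes interpolation across it deterministically
    biased.  The combined SE propagates the Poisson counting noise of both
    profiles and the sampling uncertainty of their plateau levels; for two
    profiles drawn from one dimensionless model the z-scores are then
    approximately standard normal.
    """
    k = min(len(a), len(b))
    if k == 0:
        raise DomainError("cannot compare empty profiles")
    dN = a.N[:k] - b.N[:k]
    se = np.sqrt(_station_se(a, k) ** 2 + _station_se(b, k) ** 2)
    tiny = 1e-12 * max(1.0, float(np.abs(dN).max()))
    return CollapseComparison(dN=dN, se=np.maximum(se, tiny), z=np.abs(dN) / np.maximum(se, tiny))


def normalize_profile(
    profile: DensityProfile,
    n0_override: float | None = None,
    plateau_fraction: float = 0.5,
    tangent_window: int = 5,
    smooth_window: int = 5,
) -> NormalizedProfile:
    """Run the full normalization: baseline, two-line r_cz, plateau edge R_p.

    ``n0_override`` substitutes an externally supplied plateau density (the
    polar density can be overestimated in some preparations, e.g. mouse
    flat-mounts) while keeping the geometric construction otherwise intact.
    """
    baseline = estimate_baseline(
        profile, plateau_fraction=plateau_fraction
    )
    if n0_override is not None:
        if not n0_override > 0:
            raise DomainError("n0_override must be positive")
        baseline = Baseline(
            n0=float(n0_override),
            intercept=float(n0_override),
            slope=0.0,
            sd=baseline.sd,
            extent=baseline.extent,
            n_points=baseline.n_points,
        )
    r_cz = locate_r_cz(profile, baseline, tangent_window=tangent_window)
    r_p = locate_R_p(
        profile, baseline, r_cz, smooth_window=smooth_window
    )
    return to_dimensionless(
        profile,
        r_cz=r_cz,
        n0=baseline.n0,
        r_p=r_p,
        baseline_sd=baseline.sd,
        provenance={
            "method": "two-line",
            "baseline_slope": baseline.slope,
            "plateau_extent_mm": baseline.extent,
            "plateau_points": baseline.n_points,
        },
    )
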
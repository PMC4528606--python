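# optlens

Ordered pull-through (OPT) modelling of radial cell-density profiles in the
mammalian lens epithelium.

## The problem

The lens epithelium is a monolayer on the anterior inner surface of the lens
capsule.  Cells proliferate throughout it — modestly in the central zone
(CZ), maximally in the peripheral germinative zone (GZ) — and exit at the
meridional rows (MR) to become lens fibre cells.  Flat-mounted preparations
show a characteristic radial density pattern: a flat central plateau, a rise
beginning near 80% of the CZ radius, a sharp peak just outside the CZ/GZ
boundary, and a decline towards the MR.  Lenses of different mammals differ
in size by almost an order of magnitude (mouse ≈ 2 mm, bovine ≈ 18 mm), so
quantitative comparison requires dimensionless coordinates.

## The model

With `R = r / r_CZ` and `N = n / n0` (radius scaled by the CZ radius,
density by the plateau density), a steady-state balance between per-capita
net cell gain (rate α in the distal CZ, β in the GZ, per day) and a
spatially invariant radial pull-through flux (parameter `k*`, mm/day) gives

    dN/dR = N (γR − 1)/R,   γ = rate · r_CZ / k*,

with γ = γ_CZ on (R_p, 1] and γ = γ_GZ on (1, R_peak], and a post-peak
decline `dN/dR = −N/δ` towards the MR.  Solving piecewise from `N(R_p) = 1`:

    N = 1                                      R ≤ R_p
    N = (R_p/R) · exp(γ_CZ (R − R_p))          R_p < R ≤ 1
    N = N_CZ (1/R) · exp(γ_GZ (R − 1))         1 < R ≤ R_peak
    N = N_peak · exp(−(R − R_peak)/δ)          R > R_peak

The ratio γ_GZ/γ_CZ equals β/α.  Rates connect to measurable quantities via
`β = 24 I / T` (proliferation index I as a fraction, cell-cycle time T in
hours) and `k* = β r_CZ / γ_GZ`.  For ageing, two empirical rules extend the
model: `n_CZ × r_CZ` is conserved as the lens grows, and γ_GZ declines
linearly with adult age while β/α stays fixed.

## What the package provides

- `optlens.model` — the piecewise closed forms, rate conversions, and an
  independent ODE-integration oracle for verification.
- `optlens.normalization` — plateau baseline, the two-line intercept
  construction for `r_CZ`, plateau-edge detection (`R_p`), dimensionless
  transform, and a scaling-collapse comparison.
- `optlens.fitting` — least-squares estimation of (β/α, γ_GZ, δ) on
  normalized profiles, pooled multi-profile fits, a joint dimensional
  refinement (`fit_profile`), and case-resampling bootstrap intervals.
- `optlens.ageing` — the `n_CZ × r_CZ` invariant, the γ_GZ(age) relation,
  and full profile prediction at arbitrary ages.
- `optlens.synthetic` — a seeded generator of flat-mount-like profiles
  (Poisson counting noise per sampling field) with species presets, so every
  stage is testable without laboratory data.
- `optlens.io` / `optlens.cli` — delimited-table readers/writers, JSON
  serialization, a pipeline driver and the `optlens` command
  (`simulate`, `normalize`, `fit`, `age-predict`, `pipeline`).

## Worked example

`examples/fit_synthetic_profile.py` simulates a bovine-scale profile with
Poisson counting noise, normalizes it and fits the model:

```
simulated 67 radial bins out to 6.08 mm (true r_CZ = 4.5 mm, plateau 4500 cells/mm^2)
two-line initial estimates: r_CZ = 4.504 mm, n0 = 4426 cells/mm^2, R_p = 0.93
refined fit: r_CZ = 4.632 mm, n0 = 4443 cells/mm^2
  beta/alpha = 2.253   (generating value 2.16)
  gamma_GZ   = 5.915   (generating value 5.13)
  delta      = 0.102   (generating value 0.10)
  SSR = 9.661e+06 over 67 points, converged = True
```

β/α ≈ 2.3 says the germinative zone gains cells roughly twice as fast per
capita as the distal central zone; γ_GZ ≈ 5.9 measures that gain relative to
pull-through; δ ≈ 0.1 sets how sharply density falls beyond the peak.  The
other examples cover rate conversions (`rate_conversions.py`), cross-species
scaling collapse (`species_scaling.py`) and ageing predictions
(`ageing_prediction.py`).

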
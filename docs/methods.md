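# Methods

## Model and assumptions

The epithelium is treated as a two-dimensional, axially symmetric cell
population on the flat-mounted capsule, in quasi-steady state: age-related
change is slow compared with cell turnover, so at each radius the net
per-capita cell gain balances the divergence of a radial pull-through flux.
Pull-through is spatially invariant (one parameter `k*`, mm/day, for the
whole epithelium) and apoptosis is neglected — measured apoptotic counts in
lens epithelia are of order tens of cells against ~5×10⁵ cells, far below
every other term in the balance.  Because the data come from flat mounts,
the two-dimensional polar representation is taken as given; no
three-dimensional shell-to-plane correction is applied, and the 2π factor
common to every annulus term cancels and is never represented.

In dimensionless coordinates (R = r/r_CZ, N = n/n0) the balance is
`dN/dR = N(γR − 1)/R` with `γ = rate·r_CZ/k*` per zone.  The post-peak
(transitional zone / meridional rows) branch is `dN/dR = −N/δ`: a single
dimensionless gradient coefficient `1/δ`, with no additional geometric 1/R
factor.  The active decline towards the MR is much stronger than the
circumferential dilution a 1/R factor would describe, and one coefficient is
the most parsimonious form; the ODE oracle integrates exactly this form, so
closed forms and oracle are verified against one another rather than against
a typeset equation.

Units are fixed throughout: mm, cells/mm², days for rates, hours for the
cell-cycle time.  The proliferation index is a fraction internally (percent
only at user interfaces).  Ages are normalised to days internally
(month = 365.25/12 d, year = 365.25 d).

## Normalization (two-line construction)

* Baseline: candidate plateau = samples at radii below half the peak
  position; least-squares line, refitted once after discarding points more
  than 2 residual SDs above it.  `n0` is the mean of the retained samples;
  the slope is reported and expected near zero.  The peak position uses the
  last index attaining the maximum so that perfectly flat and monotone
  profiles are handled uniformly; for monotone (human-like) profiles the
  final sample is the peak.
* `r_CZ`: intersection of the baseline with a least-squares tangent over 5
  samples centred on the rising flank's crossing of the mid-level between
  baseline and peak (the last crossing before the global peak, robust to
  counting noise).
* `R_p`: the profile is smoothed with a centred 5-sample moving average;
  the departure point is where the smoothed density first leaves the
  plateau level by more than max(2×baseline SD, 1% of n0) — the floor keeps
  the test meaningful on noiseless data — with the crossing radius linearly
  interpolated.  Only radii below r_CZ are scanned, so R_p < 1 by
  construction; a fallback (last sample before r_CZ, with a warning) covers
  profiles whose rise never clears the band inside r_CZ.

The construction is deliberately model-free, and on sampled convex flanks it
carries a small structural bias: applied to an exact model curve the
mid-level tangent intercept lands at ≈0.99·r_CZ (and far lower, ≈0.73·r_CZ,
on shallow monotone human-like shapes, where the construction is intrinsically
ill-suited).  The estimates are therefore treated as initial values.

## Fitting

`fit_opt_params` minimises unweighted squared residuals in N over
(γ_GZ, β/α[, δ]) with R_p fixed from the normalization and R_peak fixed at
the observed argmax (both overridable; R_peak may be freed).  Positive
parameters are optimised in log space; a deterministic 8-point multistart
(log-uniform γ over [0.5, 10], δ over [0.02, 1]) guards against local minima
of the piecewise model.  δ is fitted only when at least 3 points lie beyond
the peak; otherwise the model is truncated there and those points dropped.
An inverse-variance weighting option (per-field Poisson variance n/A) exists
but is off by default.

`fit_profile` is the recommended estimator: it fits the dimensional curve
`n0·N(r/r_CZ)` directly, refining (n0, r_CZ, R_p and, when a peak exists,
the R_peak knot) jointly with the γs, seeded by the two-line construction.
On noiseless model data this removes the construction bias entirely
(recovery to optimiser precision).  Simulation at realistic counting noise
showed the free knot clearly preferable to pinning the peak at the observed
argmax (the argmax jumps bins under noise); the residual γ_GZ uncertainty is
dominated by a finite-sample ridge linking γ_GZ, r_CZ and R_peak, and sits
somewhat above the asymptotic information bound — no estimator variant tried
(inverse-variance weighting, iterative reweighting, exact Poisson
likelihood, log-density residuals) improved materially on unweighted least
squares along this ridge.

`pooled_fit` shares (γ_GZ, β/α[, δ]) across profiles with per-profile
R_p/R_peak, minimising the total SSR.  `bootstrap_ci` case-resamples profile
points and repeats the entire fit per resample (same peak policy),
reporting percentile intervals; degenerate resamples are skipped and
counted.  Simulation shows these intervals are conservative (they over-
rather than under-cover), as case resampling on a fixed design tends to be.

## Ageing layer

`n_CZ × r_CZ = C` is estimated as the mean of the observed products (cv
reported; flagged when a single entry).  γ_GZ(age) is a least-squares line —
the available anchors (≈2.0 in young adults declining to ≈1.1 in old age)
determine a line and nothing constrains a richer form — with extrapolation
outside the fitted range permitted but warned.  β/α is held age-invariant.
Predictions set γ_GZ from the line, γ_CZ from β/α, and n_CZ = C/r_CZ(age)
so the conservation law holds exactly by construction; the post-peak branch
is omitted by default, matching the treatment of aged human profiles where
the GZ/MR boundary is not resolvable.  The invariant is demonstrated for
mouse; applying it to other species is an extrapolation the caller opts
into.

## Synthetic data generator

The generator emulates nuclei counting on flat mounts: radial bins of width
0.05·r_CZ by default, one counting field per bin with area sized for ~200
expected plateau nuclei, counts drawn Poisson with mean n(r)·A and density
recorded as count/A (counts and areas stored).  Profiles extend to
1.35·r_CZ: the post-peak decline reaches an intermediate density (N ≈ 0.7
with the default δ) there, which is where the meridional rows terminate;
sampling further would measure essentially cell-free capsule.

Species presets share one dimensionless parameter set — β/α = 2.16,
γ_GZ = 5.13 (hence γ_CZ = 2.375), R_p = 0.8, R_peak = 1.2 — with δ = 0.1
chosen arbitrarily (no measured value exists).  Scales anchor on reported
densities where available: rabbit plateau 3500 and mouse plateau 5300
cells/mm²; the rat plateau is set so the shared peak ratio reproduces the
reported 15900 cells/mm² rat peak; bovine (4500 cells/mm², r_CZ 4.5 mm) is
interpolated.  A single dimensionless set cannot reproduce both the
reported mouse plateau and mouse peak (their ratio differs from the shared
2.99; the polar density in mouse preparations is known to be overestimated),
so the mouse preset anchors on its plateau.  The human preset is monotone:
β/α = 1, γ_GZ = 2.0, R_p = 0.5 — note γ·R_p = 1, the slowest admissible
departure — no post-peak branch, and plateau chosen so the final-point
maximum is the reported 8650 cells/mm².

What the generator does not emulate: flat-mount stretching or wedge
distortion, spatial correlation between fields, segmentation errors, the
irregular bin spacing of real image series, or any real-data deviation from
the model family (e.g. whatever makes measured human profiles depart their
plateau more abruptly than the tangential model shape can).  Passing
closed-loop tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not robustness to those artefacts.

## Numerical choices

* ODE oracle: DOP853 with rtol 1e-11 / atol 1e-12, integrated piecewise per
  branch so breakpoints are never stepped across.
* Optimisers: Levenberg–Marquardt on log/logit-transformed parameters
  (positivity and R_p ∈ (0,1) enforced by the transform); invalid parameter
  regions return large finite residuals; log-parameters clipped at ±60
  before exponentiation.
* The scaling-collapse comparison pairs matched sampling stations (bins are
  fractions of each lens's r_CZ by design) rather than interpolating — the
  sharp peak makes interpolation across it deterministically biased — and
  its combined SE propagates both the per-station Poisson error and the
  sampling uncertainty of the plateau level.
* Ties and degeneracies: mid-level crossings use the last crossing before
  the peak; tied maxima resolve to the outermost sample; bootstrap
  resamples without identifiable parameters are skipped and counted.

## Known limitations

* At the default coarse sampling (27 bins) with counting noise, the
  breakpoint structure is weakly identified and individual noise draws can
  favour a structurally wrong mode (e.g. an implausibly low β/α); finer
  sampling (bin ≈ 0.02·r_CZ) resolves this and is used throughout the
  examples and simulation studies.
* The two-line construction is unreliable on shallow monotone profiles
  (human-like); estimates there should be read as initial values only.
* γ_GZ from a single noisy profile carries ~6–9% relative uncertainty at
  ~200 counts/bin and 80 bins; pooling profiles is the effective remedy.
* The bootstrap intervals are conservative rather than exactly calibrated.
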
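# Methods

This note documents the models behind `proxyshift`, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not establish about real records.

## Time conventions

All ages are calibrated years before 2000 ("cal yrs b2k") and increase with
depth; calendar time therefore runs opposite to the age axis. Every analysis
that cares about direction (trend derivatives, signal definitions such as
"step at age t₀") is computed on increasing calendar time internally and
reported with calendar-time signs; conversion to year CE is left to the
reporting layer.

## Chronology ensemble

**Model.** Each dated horizon contributes an independent Gaussian age error
at its 1σ value. Sources quote errors at different conventions — 2σ is
typical for marine records, 3σ for varve-counted or mixed lake chronologies —
so `DatedHorizon` stores the 1σ value plus the stated convention multiplier,
and the CSV loader performs the division. Marine reservoir corrections are a
plain age shift with quadrature error combination (default ΔR = 140 ± 60 yr,
a regional deep-water value).

**Sampler.** A draw perturbs every horizon age, projects the perturbed
vector onto the monotone cone with least-squares isotonic regression
(pool-adjacent-violators, via `scipy.optimize.isotonic_regression`), and
interpolates piecewise-linearly onto the depth grid. Isotonic projection was
chosen over rejection sampling because rejection is unbounded when errors
are large relative to date spacing; projection also leaves draws unchanged
whenever the perturbed ages are already monotone, which is the common case
at realistic error/spacing ratios. Weak ties after projection receive
increments of 10⁻⁹ × record span so every draw is strictly increasing.

**What this is not.** The sampler is a surrogate for Bayesian accumulation
modelling (BACON-style): it reproduces depth-dependent dating uncertainty,
which is all the downstream stages consume, but has no accumulation-rate
prior, no section memory, and no calibration-curve multimodality (horizon
errors are Gaussian). Extrapolation beyond the outermost dates is refused by
default and available by flag (constant-rate extension).

**Calibration.** At a dated horizon the draw distribution is N(observed, σ²)
while the truth is observed − ε with ε ~ N(0, σ²), so the 90% envelope
covers the truth at exactly 90% when projection is inactive; between
horizons the same ratio holds for linear interpolation of independent
errors. The test suite verifies ~90% ± 5% coverage over 200 replicate
synthetic chronologies; projection bites only when perturbations invert
adjacent dates, which at the preset error/spacing ratios is rare and costs
about one coverage point.

## Derived proxies

Standard identities, kept unit-aware: flux = concentration × mass
accumulation rate; TOC-normalisation divides by TOC/100; the sterol index is
c/(c+β) (scale-invariant, in [0,1], undefined when both sterols are zero);
fractional sterol = sterol flux × index, collapsing two correlated sterol
variables into one PCA input; Cd:Ti sums XRF counts into ≥1 mm bins before
dividing (trace-element count rates are too noisy at native 0.1 mm
resolution), dropping and logging zero-Ti bins; relative abundances are
percentages of per-sample totals, with a warning below the 400-valve
quantitative minimum.

The assemblage index applies a square-root transform to proportions (0–1,
not percentages — standardisation removes the constant factor, so the choice
is cosmetic and documented rather than consequential), z-scores each taxon,
takes correlation-matrix PCA scores, and combines the first two score series
as (v₁·PC1 + v₂·PC2)/(v₁+v₂). Default weights (0.34, 0.27) are the variance
fractions of the study system this package was built around; one weight may
be zero (the index degenerates to the other axis) but not both.
Below-detection biomarker values are treated as exact zeros; half-detection-
limit substitution can be applied upstream by the caller.

## Monte Carlo propagation

Draw i pairs the i-th age-model realization with an independent
measurement-noise realization — the simplest joint propagation of the two
error sources; relative noise multiplies (v·(1+ε)), absolute noise adds.
Each perturbed (age, value) path is linearly interpolated onto a common time
grid (default 20-yr steps over the overlap of the series' median age spans,
inset by two steps so dating jitter rarely pushes a draw's span off the grid
edge). Grid times not covered by every draw are rejected and logged, so each
summary column holds exactly n draws: the 2D frequency density (50
equal-width value bins by default) conserves draws per time bin, and the
median / 5th–95th percentile envelope is defined everywhere it is reported.
The envelope holds 90% of draw values per grid time by construction, up to
percentile-interpolation ties — this is the envelope-calibration check the
acceptance script recomputes at n = 10,000.

## PCA synthesis and envelope propagation

Median series are z-scored over the common grid and the correlation matrix
eigendecomposed (`numpy.linalg.eigh`); components are ordered by decreasing
eigenvalue. Signs are fixed by an orientation proxy on PC1 (diatom flux for
marine-style records, δ¹⁵N for lake-style, so that PC1 reads as "production"
or "seabird influence" respectively); higher components get their
largest-magnitude loading made positive. Scale invariance is inherited from
z-scoring.

Propagating the per-proxy envelopes onto PC1 has no canonical formula; the
declared convention, isolated in `fractional_mean_uncertainty` /
`propagate_pc_envelope` so alternates can be swapped, is:

    f_i  = mean over time of (p95_i − p5_i) / (2·|median_i|)
    h(t) = |PC1(t)| · Σ_i |l_i|·f_i / Σ_i |l_i|,   PC1 ∓ h(t) = envelope

with the series' mean |median| substituted in the denominator wherever the
median is below 10⁻⁶ of that scale, so near-zero crossings do not blow up
the fraction. The magnitude (Y) envelope and the dating (X) half-width —
interpolated from the age ensemble's 90% band through the median age model —
are reported separately; temporal claims should cite the latter.

## Trend model and change detection

**Model.** y_i = f(t_i) + e_i with f a cubic B-spline expansion (default
basis dimension 20, open uniform knots; records typically carry 80–300
points, and the penalty, not the knot count, controls effective complexity)
penalized by its integrated squared second derivative, computed exactly by
Simpson's rule per inter-knot interval (B″ is piecewise linear). Errors are
N(0, σ²V(φ)) with the continuous-time AR(1) correlation φ^|Δt| (φ =
correlation at a 1-year lag), whitened analytically in O(n) using the AR(1)
innovations form.

**Smoothing selection.** λ is chosen by minimising the profiled restricted
likelihood (REML) or the GCV score on the whitened model, by bounded scalar
search over log₁₀λ ∈ [−7, 9]. φ is profiled on a fixed grid
{0, 0.5, 0.8, …, 0.999} and always judged by the restricted likelihood at
its per-φ optimal λ, whichever criterion chose λ — GCV alone is not a sound
objective for a correlation parameter. REML is the default; GCV is the
per-series fallback for heteroscedastic series that REML over-smooths (the
pipeline defaults Cd:Ti and cholesterol to GCV). No automatic over-smoothing
detector is attempted; the choice is per-series and explicit. The φ = 0 path
(and `car1=False`) reduces to the independent-error penalized spline, which
is cross-checked against mgcv's REML cubic regression spline in the test
suite (RMSE below 2% of the response SD on the fixture; observed ≈ 0.1%).

**Uncertainty and significance.** Trend uncertainty uses the Gaussian
coefficient posterior β ~ N(β̂, σ̂²(X′X + λS)⁻¹) with σ̂² = RSS/(n − edf) on
the whitened scale. Posterior trend curves are drawn on a 200-point uniform
grid; first derivatives come from finite differences per draw (central
inside, one-sided at the ends); the 95% band is formed from pointwise draw
quantiles, or optionally widened by a max-t critical value for simultaneous
coverage (the pointwise band is the default; which of the two classic
applications used is ambiguous, and simultaneous inference is strictly more
conservative). A significant change is any run of grid points where the
band excludes zero — with a tolerance of 10⁻⁷ × (response scale / time span)
so float fuzz on exactly-flat fits never triggers — and each run is
summarised by its midpoint age and calendar-time sign.

The default 1,000 posterior draws give stable derivative quantiles; 20
draws (the classic display convention, available via `--paper-faithful` or
`n_post=20`) are too few for reliable tail quantiles and are intended for
visualisation. Degenerate posteriors (exactly noiseless data) fall back to
point-mass draws; the RSS in both criteria is floored at the square of
10⁻¹³ × the response magnitude to keep log-likelihoods finite on data the
spline interpolates exactly.

**Error calibration.** On pure-noise series the false-positive rate (any
significant interval per series at the 95% level) is controlled at ≤10%
across seeded replicates — wider than the nominal 5% to absorb the Gaussian
posterior approximation and multiplicity across the grid. Power against a
lake-preset logistic step is ≥90% with the step age recovered inside the
dating envelope plus transition half-width.

## Synthetic records

The generator emulates the two-record study design: a marine record of
4,000 yr over 540 cm (11 dated horizons every 54 cm, errors stated at 2σ,
three flux series at ±7.5% relative noise, samples every 5 cm) and a lake
record of 6,000 yr over 177 cm (10 horizons, 3σ convention, samples every
2 cm) with four series at the stated uncertainties: Cd:Ti 2% relative, δ¹⁵N
0.5‰ absolute, fractional sterol 0.001 mg cm⁻² yr⁻¹ absolute, diatom index
10% relative. The 10% index uncertainty is read as multiplicative, like the
marine ±7.5%, and the preset keeps the index series strictly positive so
relative noise and fractional envelope widths stay well-defined. The 1σ
dating error grows linearly with depth (15→60 yr marine, 20→70 yr lake),
emulating the usual downcore growth of calibrated-age uncertainty at
magnitudes small against date spacing.

The signal library is deliberately minimal — constant, clamped linear ramp,
hard step, logistic step — because the scientific questions downstream are
about abrupt transitions and gradual declines. The marine preset injects a
production collapse at 2200 b2k (production proxies step down with
different transition widths and small background drifts; HBI III steps up),
giving the (+, +, −) PC1 loading structure; the lake preset injects a
colonisation step at 4300 b2k in all four series. True accumulation is
linear in depth; age-model truth is known exactly. All randomness flows
from one integer seed through `numpy.random.default_rng`; no global state.

**What passing tests show — and don't.** Recovery and calibration results
on these records demonstrate the statistical machinery is correct under its
own assumptions: Gaussian errors, known noise magnitudes, linear truth
accumulation, signals inside the span of the spline basis. They do not
establish performance under calibration-curve multimodality, non-Gaussian
or drifting measurement error, bioturbation smoothing, hiatuses, or signal
shapes outside the library. Synthetic histories are stand-ins, not
reconstructions of any real proxy's past.

## Problem sizes

Defaults mirror the full-scale analysis (10,000 Monte Carlo draws, 200-point
derivative grids). The test suite scales replicated experiments to desk
scale as its own design choice — 100–500 draws inside replicate loops, 100
replicates for power/type-I rates, 200 for chronology coverage — sizes at
which the binomial noise on each estimated rate is comfortably inside the
asserted bands.

## Known limitations

- The chronology sampler is a surrogate; it should not be used where the
  accumulation-rate prior itself matters (e.g. hiatus detection).
- PC1 envelope propagation is a declared convention, not an estimate of the
  sampling distribution of PC scores; a full alternative would re-run PCA
  per Monte Carlo draw, at the cost of loading-sign alignment issues.
- The trend model is Gaussian-response only, with a single univariate
  smooth; no tensor smooths, no non-Gaussian families.
- GCV with CAR(1) shares φ selection with REML (see above); series where
  correlation and heteroscedasticity interact strongly deserve a dedicated
  analysis.
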
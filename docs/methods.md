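# Methods

This note documents the models, numerical choices and limitations of the
package in one place. Everything quantitative stated here is computed by the
test suite or the example scripts.

## Growth-rate reconstruction

A core is a sequence of radiocarbon-dated depths. Sorting one core's points by
depth must sort ages non-decreasingly; violations are rejected when the table
is read, because an age–depth inversion means the dates cannot bound growth
intervals. Consecutive points bound a segment with rate Δdepth/Δage (mm/yr);
the older bound of one segment is the younger bound of the next, so n dated
points yield n−1 samples and total segment length telescopes to the depth span
of the core. Pairs with tied ages carry no rate and are skipped with a logged
warning rather than discarding the core. Core identity is
`study::core` — core names repeat across studies, and the reserved `::`
separator keeps the mapping injective.

Two filters define the analysis set. The age cap drops samples whose older
bound exceeds 11,700 yr BP (bound inclusive: "greater than" is read strictly).
The outlier filter retains the central 97% of the pooled rate distribution,
cutting 1.5% per tail; quantiles use linear interpolation between order
statistics so retained counts are bit-reproducible. The filter is one-pass by
definition: because the cut quantiles of the filtered set move inward, exact
idempotence is impossible for a strict central-band filter on continuous data,
and re-application would trim a few further points. Pooling is global, not
per-region. Regional trends use a degree-1 LOESS (tricube weights over the
nearest `span` fraction of points, default 0.75) with a pointwise 95% band
from the weighted-least-squares variance; regions with fewer than 10 samples
are refused.

## Orbital solution and insolation

Orbital elements come from the classical Berger-type trigonometric series,
with coefficient tables shipped as commented CSVs: obliquity (constant
23.320556° plus 20 leading cosine terms), the 19-term eccentricity/fixed-
perihelion vector, and the general precession in longitude (linear rate
50.439273″/yr plus 10 leading sine terms). Truncation errors over the
Holocene are below 0.02° in obliquity and below 5×10⁻⁴ in the precession
index — far inside the tolerances at which these quantities are quoted. The
climatic precession index is `e·sin ϖ` with ϖ the heliocentric longitude of
perihelion from the moving equinox (present value ≈ 102°, index ≈ +0.016).

Daily-mean insolation is the standard geometric form
`(S/π)(d̄/d)²(H₀ sinφ sinδ + cosφ cosδ sinH₀)` with declination
`sinδ = sinε sinλ`, sun-hour angle `H₀ = arccos(−tanφ tanδ)` clamped to [0, π]
(polar night is exactly zero, polar day integrates the full 24 h), and the
inverse-square distance factor `((1 + e cos(λ−ϖ_g))/(1−e²))²` with ϖ_g the
geocentric perihelion longitude. Calendar: fixed 365-day year, standard month
lengths, vernal equinox at day 80; day-of-year maps to true solar longitude
through the third-order equation-of-center expansion. Annual means evaluate
the 12 month midpoints and weight by month length; this discretization
reproduces a 1,000-point daily quadrature to better than 1% and breaks exact
north–south symmetry at the 10⁻⁴ relative level (the analytic annual integral
is symmetric for a circular orbit). No atmospheric attenuation is modelled:
the "surface" insolation is the latitude-resolved top-of-atmosphere flux,
which is how the standard insolation computation defines it; a true
sea-surface photosynthetically-available-radiation product would need an
atmosphere and is out of scope.

## Covariate construction

All proxy records interpolate linearly inside their span and extend with the
nearest value outside it. Segment grids run T1, T1+step, …, capped at T2 with
T2 always included; sub-step segments use the endpoint ages only. Steps follow
each record's native resolution: 22 yr (TSI), 8 yr (CO₂), 70 yr (ice-rafted
debris). TSI anomalies are converted to absolute irradiance against
1365 W/m² before the insolation transform; samples partially overlapping the
TSI record average in-record age points only, and wholly-outside samples use
the nearest-value extension.

SST: a sample's site maps to the nearest grid cell with a complete series by
great-circle distance; the cell's 200-yr series is clipped to [T1, T2], the
interpolated endpoint values are appended, and the set is averaged (endpoint
mean for sub-resolution segments). Sea-level rate: the submergence curve
(positive = deeper) is interpolated at every integer year in
[⌈T1⌉, ⌊T2⌋] and the mean year-to-year difference, converted to mm/yr, is the
rate — the telescoping identity makes this the endpoint slope, which pins the
sign convention (positive = rising). Sub-annual segments fall back to the
endpoint slope directly. Volcanic forcing: monthly aerosol optical depth is
averaged to calendar years, interpolated linearly between the flanking
10° latitude bands (clamped at the outermost), scaled by 25 W/m² per unit
optical depth, summed over every 20-yr window at 1-yr stride lying fully
inside the segment, and the window sums are averaged; segments shorter than
20 yr use a single window of all available years. Windows never reach outside
the segment. Every kernel is verified against an independent brute-force loop
implementation at 10⁻⁹ absolute tolerance on 500 random cases.

The collinearity screen reports pairwise Pearson correlations (pairwise-
complete) and flags |r| > 0.7; zero-variance columns yield undefined (NaN)
correlations, reported but never flagged.

## The hierarchical model and its inference

Response: gamma with log link (the standard choice for positive, right-skewed
rates; effects are multiplicative). Latent structure: z-scored fixed effects
(weak N(0, 10²) priors; scales stored for back-transformation), RW2 smooths on
equal-width bins (default 20 per covariate; second-difference penalty of rank
n_bins−2, a soft sum-to-zero constraint with precision 10⁴ on the bin mean,
and a faint 10⁻⁴ ridge that makes the prior proper in its linear null
direction), iid group effects, and the SPDE–Matérn field (smoothness ν=1)
assembled from lumped-mass/stiffness P1 finite elements on a Delaunay mesh
(fine lattice near sites, coarse lattice over a buffered hull; sites are mesh
nodes, so barycentric projection is exact at sites). Sites are projected to a
local tangent plane in km; distances enter the Matérn kernel, so the
projection is part of the model definition and adequate at the regional
extents used here.

Hyperparameters (gamma shape; one sd per RW2 term and per iid group; spatial
range and sd) carry log-normal priors: log sd ~ N(log 0.3, 1.5²) for
random-effect scales, log shape ~ N(log 5, 1.5²), log range ~ N(log(0.3 ×
site-domain diameter), 1²). Each RW2 term has its own hyperparameter.

Inference is a nested Laplace approximation. The gamma log-likelihood is
log-concave in the linear predictor, so the inner Newton solve (dense
Cholesky of prior-precision + BᵀWB, step-halving line search) is well behaved;
the outer L-BFGS maximizes the Laplace log marginal posterior over the log
hyperparameters (bounded at 150 evaluations by default, warm-started modes).
Hyperparameter uncertainty is integrated by an axis design around the mode —
per axis, curvature is probed at ±0.3 and integration points placed at
±1.65 posterior sd (clipped to [0.15, 2.5]) — and posterior draws come from
the resulting mixture of Gaussians, weighted by marginal-posterior mass. This
is the same design philosophy as the CCD integration of nested-Laplace
software. A non-converged inner or outer optimization is flagged on the
result, never silently ignored. Draws feed everything downstream: interval
summaries, WAIC (`−2(lppd − p_waic)` from the pointwise log-likelihood
matrix), and LOO-PIT (importance weights 1/p(yᵢ|draw), Pareto-smoothed via
arviz, with per-observation reliability diagnostics k̂ > 0.7 flagged).

Effect classification follows the nested-interval display convention of
coefficient plots with 50/80/90% bars: `classify_effect(draws, level)` labels
a coefficient credible-positive/negative when the stated interval excludes
zero. An effect is called *strong* when the intervals at all displayed levels
— i.e. the 90% interval — clear zero; otherwise it is not credibly different
from zero. The recovery tests use this rule.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the real inputs at their native
resolutions: a 9,389-yr TSI anomaly record at 22-yr steps; CO₂ at 8-yr steps
sweeping 255–335 ppmv across the age span (deliberately wider than the real
pre-industrial Holocene range so that the bimodal CO₂ effect is identifiable
across both bumps); ice-rafted debris at 70-yr steps with a 1,470-yr
Bond-cycle sinusoid; monthly stratospheric aerosol optical depth in 10°
bands from Poisson eruptions (3 per century, lognormal magnitudes, 12-month
e-folding decay, 20° latitudinal spread, background 0.002); a 1°×200-yr SST
grid with a latitudinal gradient, a mid-Holocene warm anomaly (+1.2 °C,
centred 8,000 yr BP) and missing cells (a contiguous block plus 8% dropout)
to exercise the nearest-valid-cell search; and per-region sea-level
submergence curves with deglacial rates near 10 mm/yr that stabilize at
~5,500 yr BP in the Pacific/Indian basins but only near the present in the
Atlantic. Cores draw gap lengths lognormal with median 410 yr; ages are
clipped to the configured span; depths are accumulated from the drawn rates,
so segment reconstruction returns the simulated rates exactly.

The forward model writes log-mean growth as intercept (log 3 mm/yr) + 0.10 ×
sea-level rate + null SST and volcanic coefficients + a bimodal CO₂ effect
(Gaussian bumps at 275 and 325 ppmv, sd 9, amplitude 0.25) + a declining
ice-rafted-debris effect + a mid-Holocene age hump + a mild segment-length
trend + a Matérn field (sd 0.25, range 1,200 km) + iid effects
(sd 0.05–0.20) and draws rates from a gamma with shape 8. Every generator
derives its stream from the scenario seed by a labelled hash, so adding a
generator never perturbs existing output, and identical (config, seed) give
byte-identical files.

What passing tests therefore show: the pipeline's kernels match their
definitions; the fitter recovers parameters from data generated by its own
model class at desk scale (40 sites, ~300 samples). What they do not show:
robustness to dating error, reservoir corrections, proxy biases,
non-gamma residuals, or real spatial sampling patterns — none of which the
generator emulates.

## Problem sizes and numerical choices

Desk-scale defaults were chosen so a full simulate–filter–fit replicate runs
in ~10 s and the complete suite in minutes: mesh edges 350/1,200 km with a
700 km buffer (≈600–700 nodes), 800 posterior draws, 150 marginal
evaluations, 20 bins per smooth. A paper-scale layout (~290 sites, ~1,900
samples) is provided (`paper_scale_scenario`) but not exercised by the tests.
The structural recovery checks size their inputs for adequate power: 900
observations for the bimodal-smooth check (20 bins over an 80 ppmv range is a
4 ppmv bin width, and the ±1-bin criterion needs the posterior curve to
localize both bumps to ~4 ppmv), 150 per replicate for the WAIC screen, and
1,200 for the network optimum.

Degenerate inputs: tied ages skip a segment; constant covariates cannot be
binned or z-scored and raise; all-missing SST grids raise; collinear site
sets are refused by the mesher; empty data reduce the fit to its prior (a
tested property). Determinism: every stochastic step takes an explicit seed;
fits are reproducible bit-for-bit given (data, seed).

## Known limitations

* The Laplace posterior is Gaussian conditional on hyperparameters; strongly
  skewed latent posteriors (tiny groups, extreme shapes) are approximated,
  not exact. Coverage is validated empirically on synthetics (90% intervals
  cover ≥80% across replicates), not guaranteed analytically.
* At the 80% level, a correctly-calibrated interval excludes a truly null
  effect in ~20% of replicates — a sampling property of any calibrated
  procedure, visible in the recovery tests and the reason effect *strength*
  is judged at the widest displayed interval.
* The equirectangular site projection distorts at near-global extents; a
  great-circle mesh would be needed for a genuinely global fit.
* The truncated orbital series is Holocene-grade; deep-time (> 1 Myr) use is
  refused.
* The network reports point predictions only; its partial-dependence curves
  carry no uncertainty bands.
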
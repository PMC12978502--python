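# holoreef

Holocene coral-reef growth analysis: reconstruct reef growth rates from
radiocarbon-dated core intervals, derive environmental covariates from paleo
records, fit a spatio-temporal hierarchical Bayesian gamma model, and estimate
nonlinear growth responses with a small feed-forward network.

## The scientific problem

Reef cores dated through the Holocene (the last 11,700 calibrated years before
present, yr BP, with "present" = 1950 CE) record how fast coral reefs built
carbonate framework under different climates. Within a core, consecutive dated
depths bound intervals T1–T2, and the growth rate of an interval is

```
rate = segment length (mm) / (T2 − T1)   [mm/yr]
```

where the older bound T2 of one interval is the younger bound T1 of the next.
The questions: which environmental and climatic variables — sea-surface
temperature (SST), the rate of sea-level change, volcanic forcing, atmospheric
CO₂, solar irradiance, North Atlantic drift ice — drove reef growth, and what
ocean temperature was optimal?

The package answers these with a gamma generalized linear mixed model with log
link, fitted by a nested Laplace approximation:

```
rate_i ~ Gamma(s, μ_i),   log μ_i = β₀ + β·x_i + Σ_k f_k(z_ik) + w(s_i) + u_groups
```

* **fixed effects** `x`: sea-level rate (mm/yr), SST (°C), 20-yr cumulative
  volcanic forcing (W/m²), z-scored;
* **smooths** `f_k`: second-order random walks (RW2) on binned CO₂ (ppmv),
  ice-rafted debris (% lithic grains), sample mean age, and segment length;
* **spatial field** `w`: an SPDE–Matérn Gaussian Markov random field on a
  triangular mesh, precision `Q = τ²(κ⁴C + 2κ²G + G C⁻¹ G)` with marginal
  variance `σ² = 1/(4πκ²τ²)` and correlation range `√8/κ`;
* **iid effects** `u`: ocean, region, locality and core identity.

Validation uses WAIC (`−2(lppd − p_waic)`), Pareto-smoothed importance-sampled
leave-one-out probability integral transforms (LOO-PIT), and credible-interval
effect classification. A two-hidden-layer perceptron (20 and 10 units; 70/15/15
train/test/validation split, 30 restarts, early stopping) supplies
partial-dependence curves for the nonlinear SST and sea-level responses. A
Berger-type trigonometric orbital solution (obliquity, eccentricity, climatic
precession `e·sin ϖ`) converts total solar irradiance into latitude-resolved
annual insolation.

Everything runs on synthetic data with known ground truth generated by
`holoreef.synthetic`; no downloads are required.

## Worked example

```bash
python examples/04_spatial_model.py
```

prints (seed 6 of the default desk-scale scenario, ~360 samples at 40 sites):

```
fixed effects (original units, per-unit of covariate):
  sl_rate  posterior +0.0972 +/- 0.0130 [truth +0.10] -> credible-positive
  sst      posterior -0.0384 +/- 0.0477 [truth +0.00] -> not-credible
  volc     posterior +0.0148 +/- 0.0506 [truth +0.00] -> not-credible
...
LOO-PIT Kolmogorov-Smirnov distance 0.051 (p = 0.25)
```

Read: the fit recovers the generating sea-level-rate coefficient (+0.10 per
mm/yr of sea-level rise on the log-growth scale) and classifies it as credibly
positive, while the truly null SST and volcanic effects straddle zero; the
near-uniform LOO-PIT says the gamma predictive distribution is calibrated.
The other examples cover the orbital/insolation solver (`01`), record
reconstruction and filtering (`02`), covariate construction and the
collinearity screen (`03`), and the neural network's recovery of a 25 °C
growth optimum (`05`).

## Layout

```
src/holoreef/
  orbital.py     trigonometric orbital solution (+ data/ coefficient tables)
  insolation.py  daily/monthly/annual mean insolation geometry
  records.py     dated points -> growth samples; filters; LOESS trends
  covariates.py  paleo series, SST grid, sea level, volcanic windows
  spatial.py     mesh, SPDE precision, RW2 penalties
  model.py       gamma GLMM via nested Laplace; WAIC, LOO-PIT, classification
  nn.py          feed-forward network + partial dependence
  synthetic.py   seeded generators with stored ground truth
  pipeline.py    simulate -> filter -> fit wrappers
```
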
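# pestmap

Spatiotemporal surveillance analysis of areal pest-complaint counts —
the kind of administrative data a city's non-emergency reporting system
(311 inquiries, housing-maintenance-code complaints) accumulates about
bed bugs, cockroaches and other urban pests, aggregated to neighborhood
areal units.

The package is written for epidemiologists and urban-health analysts who
want to answer three questions from such data:

1. **Is the burden trending, once seasonality is accounted for?**
   Monthly series are fit with a harmonic linear model whose seasonal
   amplitude varies linearly in time,

   `y_t = β0 + β1 t + (a + b t) cos(2πt/12 − ψ) + ε_t`,

   linearized to six OLS columns `[1, t, sin, cos, t·sin, t·cos]`; the
   secular trend is the t-test on β1 and the instantaneous seasonal
   amplitude `A(t) = √((β2+β4t)² + (β3+β5t)²)` is a derived quantity.

2. **Where is the burden concentrated?** Indirect standardization:
   expected counts `E_i = r n_i` with `r = Σy/Σn` per stratum (year by
   default), and the standardized incidence ratio `SIR = y/E`.

3. **How does the spatial pattern evolve?** A Bayesian hierarchical
   Poisson model per area `i` and year `t`,

   `y_it ~ Poisson(E_it e^{η_it})`,  `η_it = b0 + u_i + v_i + γ_t + φ_t + δ_it`,

   with a BYM spatial convolution (ICAR `u` + IID `v`), RW2 temporal
   trend `γ`, IID temporal `φ`, and a Knorr-Held-type space–time
   interaction `δ` of type I (IID⊗IID), II (RW2-in-time per area) or III
   (ICAR-in-space per year), compared by DIC. Inference is by
   Metropolis-within-Gibbs MCMC with conjugate precision updates;
   see `docs/methods.md` for the full model and sampler description.

A synthetic-data module generates lattices (possibly disconnected, like a
city with an island borough), latent GMRF fields and Poisson panels with
exactly this structure, so the whole pipeline is testable end to end
without downloading administrative extracts. Real-data mode reads
311-style CSV exports (configurable column dialects), GeoJSON polygons
(queen contiguity) and plain-text edge lists.

## Worked example

```python
import numpy as np
import pestmap as pm

# --- monthly trend: a declining series with decaying summer peaks -------
series = pm.simulate_monthly_series(
    72, level=875.0, trend_slope=-6.0, amplitude_start=120.0,
    amplitude_slope=-0.9, phase=0.6, noise_sd=25.0, seed=8, label="bed bug",
)
fit = pm.fit_harmonic_trend(series)
print(np.round(fit.beta, 3))
# [ 8.68488e+02 -5.84400e+00  5.34090e+01  1.00069e+02 -4.13000e-01 -6.99000e-01]
print(fit.trend_p, pm.classify_trend(fit))         # 2.2e-46  decreasing
print(pm.amplitude_at(fit, 0), pm.amplitude_at(fit, 71))   # 113.4  55.9
```

The fitted trend (−5.84 complaints/month against a generative −6) is
significantly negative, and the seasonal amplitude shrinks from ≈113 to
≈56 over the six years — the two headline quantities of the monthly
analysis.

```python
# --- panel: SIR and space-time model comparison -------------------------
lat = pm.make_lattice(6, 6, 1, population_range=(2000.0, 12000.0), seed=1)
cfg = pm.SimulationConfig(grid_rows=6, grid_cols=6, b0=0.0, tau_delta=2.0,
                          population_range=(2000.0, 12000.0),
                          interaction_type="I", seed=1)
panel, truth = pm.simulate_panel(lat, cfg, T=10)
sir = pm.sir(pm.expected_counts(panel))            # per (area, year) y/E

specs = [pm.STModelSpec(interaction_type=t, n_iter=2000, n_burn=700, seed=2)
         for t in ("I", "II", "III")]
table, best = pm.compare_models(panel, lat, specs)
print(table[["model", "dic", "p_d", "rank"]])
#      model         dic        p_d  rank
#    Model I 2237.855880 301.916563   1.0
#   Model II 2274.481503 304.389459   3.0
#  Model III 2245.079851 298.753306   2.0
rr = pm.relative_risk(pm.fit(panel, lat, best), "interaction")
```

The data were generated with an unstructured (type I) interaction, and
DIC ranks Model I first; `rr` holds the posterior-mean relative-risk
surface `E[exp(δ_it)]` per area and year (here ranging 0.28–8.5 with
median 1.00).

## Command line

```sh
pestmap simulate --config examples/demo_config.yaml --seed 3 --out out/sim
pestmap trend    --input out/sim/series.csv --out out/trend
pestmap sir      --panel out/sim/panel.csv --out out/sir
pestmap stfit    --panel out/sim/panel.csv --adj out/sim/adjacency.txt \
                 --interaction-type I --seed 3 --out out/fit
pestmap compare  --panel out/sim/panel.csv --adj out/sim/adjacency.txt \
                 --types I,II,III --seed 3 --out out/cmp
pestmap full     --config examples/demo_config.yaml --seed 3 --out out/full
```

Every run writes a `manifest.json` (inputs, hashes, seed, version); a
fixed seed reproduces all outputs bit for bit.

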
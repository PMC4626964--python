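# lakewec

Bayesian inverse estimation of lake nutrient decay rates, with
uncertainty-aware water environmental capacity (WEC) planning, for
completely-mixed lakes.

## The problem

Eutrophication management for a large, well-mixed lake (the motivating
case is Taihu Lake, China, with total nitrogen and total phosphorus as the
driving nutrients) hinges on one poorly known parameter: the first-order
in-lake decay rate `S` (1/a) that lumps settling and transformation
losses.  On an annual time scale the lake obeys the single-box mass
balance

    dC/dt = I/V − (r + S)·C,        r = Q/V,

with load `I` (t/a), volume `V` (10^8 m^3), outflow `Q` (10^8 m^3/a) and
steady state `C_eq = I/(V(r+S))`.  Given a multi-year record of
(I, Q, C*), `lakewec` inverts this relation in a Bayesian way — uniform
prior on `S`, Gaussian observation error with a vague Gamma prior on the
noise precision, Metropolis-within-Gibbs MCMC — and propagates the
posterior of `S` into the quantities managers actually use:

    WEC = C_S·V·(r̄ + S)            max load meeting target C_S, t/a
    ADC = (WEC − W)/α               allowable (controllable) discharge, t/a
    reduction = (load − WEC)/load   required load cut

evaluated at the 5%, 25%, mean, 75% and 95% posterior levels of `S`.  It
is aimed at water-quality modellers and load-allocation studies that need
defensible uncertainty bands on capacity numbers rather than a single
deterministic estimate.

## Worked example

```python
from lakewec import (MCMCConfig, PriorSpec, QualityScenario, SimulationDesign,
                     sample_posterior, simulate_series, summarize_posterior,
                     wec_table)

# a 24-year synthetic TN record at Taihu magnitudes (true S = 1.861 1/a)
series = simulate_series(SimulationDesign(seed=7))

chain = sample_posterior(series, PriorSpec(s_low=1.0, s_high=2.5),
                         MCMCConfig(seed=11))
summary = summarize_posterior(chain)
print(f"S mean {summary.mean:.3f} 1/a, 90% CrI "
      f"[{summary.q05:.3f}, {summary.q95:.3f}], sd {summary.sd:.3f}")

scenario = QualityScenario.from_mgl(2015, target_mgl=2.2,
                                    uncontrolled_load=12115.0, alpha=0.84,
                                    mean_r=series.mean_hydraulic_rate())
table = wec_table(chain, scenario, series.geometry, load=58336.0)
row = table.to_dataframe().set_index("level").loc["mean"]
print(f"WEC {row.wec_t_per_a:.0f} t/a, ADC {row.adc_t_per_a:.0f} t/a, "
      f"load reduction {row.reduction_ratio_pct:.2f}%")
```

prints

```
S mean 1.859 1/a, 90% CrI [1.729, 1.994], sd 0.081
WEC 45851 t/a, ADC 40162 t/a, load reduction 21.40%
```

The posterior mean recovers the simulation truth (1.861) within a small
fraction of the posterior SD; the capacity row says that, under this
record's hydrology, meeting a 2.2 mg/L annual-average target requires
cutting a 58,336 t/a load by about 21%, and that at most ~40,200 t/a of
controllable discharge is allowable once the 12,115 t/a uncontrolled
input (at 84% delivery) is taken out.

## Layout

- `src/lakewec/` — the library: mass-balance core (`model`), MCMC
  inference and diagnostics (`inference`), capacity algebra (`capacity`),
  synthetic-record generator and recovery harness (`synthetic`),
  Taihu reference constants (`taihu`), YAML config and CLI.
- `analysis/01_simulate.py … 04_recovery.py` — the analysis chain:
  generate synthetic records, fit both nutrients, build 2015/2020
  capacity tables, validate interval calibration.  Outputs land in
  `results/`.
- `lakewec simulate|fit|capacity|validate` — the same steps as a CLI
  (see `lakewec --help`).
- `docs/methods.md` — model assumptions, sampler design, defaults and
  limitations.

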
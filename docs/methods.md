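# Methods

## Model

`lakewec` treats a lake as a single completely-mixed box on an annual time
scale.  With storage volume `V` (10^8 m^3), annual nutrient load `I` (t/a),
outflow `Q` (10^8 m^3/a) and a first-order in-lake decay rate `S` (1/a),
the in-lake concentration `C` (t per 10^8 m^3; 1 mg/L = 100 of these
units) obeys

    dC/dt = I/V − r·C − S·C,      r = Q/V,

so `C(t) = C_eq + (C0 − C_eq)·exp(−(r+S)t)` with the steady state
`C_eq = I/(V(r+S))`.  All physics, chemistry and biology beyond hydraulic
flushing — settling, denitrification, uptake — are folded into the single
decay rate `S`, and thermal stratification and spatial structure are
ignored.  This is appropriate for large shallow lakes examined on annual
averages (the motivating system is Taihu Lake, V = 44.3 × 10^8 m^3); it is
not a seasonal or process model.

The transient solution is implemented from the linear-ODE closed form and
verified in the tests by finite-difference substitution into the mass
balance, which is the unambiguous definition of correctness.

## Inverse problem

`S` is not directly measurable; it is inferred from a multi-year record of
(I, Q, C*) by inverting the steady-state relation.  Each year's observed
concentration is modelled as

    C*_i = I_i/(V(r_i + S)) + ε_i,     ε_i ~ N(0, σ²) i.i.d.,

with a year-specific flushing rate `r_i = Q_i/V` and one common `(S, σ)`
per nutrient; TN and TP are fitted independently.  Priors: `S` uniform on
a literature-derived interval (1–2.5 /a for TN, 3–6 /a for TP for Taihu);
the noise precision `τ = 1/σ²` carries a vague Gamma(0.001, 0.001).  The
Gamma placement on the precision (rather than on σ directly) is a
deliberate choice: it is the standard vague-noise convention and makes τ
conditionally conjugate.  Both hyperparameters and the interval are
exposed in `PriorSpec`.

### Sampler

`sample_posterior` runs Metropolis-within-Gibbs:

- `S`: random-walk Metropolis restricted to the prior interval
  (proposals landing outside are rejected, which preserves the truncated
  target).  The proposal scale starts at 10% of the interval width and is
  multiplicatively tuned toward a 0.4 acceptance rate during burn-in
  only, so the post-burn-in kernel is fixed and the chain is a valid,
  bit-reproducible Markov chain under a fixed seed.
- `τ`: exact Gibbs draw from its conditional
  Gamma(a + n/2, b + SS(S)/2), where SS is the residual sum of squares.

Defaults are one chain of 50,000 iterations with 10,000 burn-in and no
thinning — conservative for a two-parameter posterior.  All randomness is
drawn up front from one `numpy` PCG64 generator, so identical
(data, prior, config) gives identical chains.

### Diagnostics

- **MC error**: batch-means standard error of the posterior mean
  (50 equal batches; sd of batch means / √50), which absorbs serial
  correlation at the batch scale.  The convergence rule is strict:
  MC error < 8% of the posterior SD.
- **Summary**: mean, SD, and 5/25/75/95% levels with linear interpolation
  between order statistics (the numpy default; documented because
  published comparisons carry three digits).
- **Fit**: R² (squared Pearson correlation of observed vs steady-state
  predicted concentrations) and Nash–Sutcliffe efficiency
  NSE = 1 − ΣSS_res/ΣSS_obs, evaluated at the posterior mean and at the
  5%/95% levels.  NSE ≤ R² always (NSE = 2αρ − α² − β² with α the
  sim/obs SD ratio and β the normalised bias, maximised at α = ρ), which
  the tests exploit as a free invariant.

The central correctness argument for the sampler is not a convergence
heuristic but an oracle: on 24-year synthetic records the MCMC mean and
credible levels must agree with deterministic two-dimensional trapezoidal
quadrature of the same unnormalised posterior (re-derived from first
principles in the test, independent of the package's density code) within
three Monte Carlo standard errors.

## Capacity planning

Management quantities are algebraic pushforwards of the posterior:

    WEC = C_S·V·(r̄ + S)         water environmental capacity, t/a
    ADC = (WEC − W)/α            allowable discharge capacity, t/a
    reduction = (load − WEC)/load

where `C_S` is the concentration target, `r̄ = Q̄/V` the long-run flushing
rate (arithmetic mean of annual outflows over the record — planning uses
the long-run rate, while the likelihood uses year-specific rates), `W` the
uncontrolled input and `α` the delivery coefficient.  Uncertainty is
propagated level-wise: WEC is evaluated at the 5/25/mean/75/95% posterior
levels of `S`.  Because WEC is strictly increasing in `S`, the level-wise
table coincides with the corresponding quantiles of the full WEC
pushforward distribution, so nothing is lost relative to sampling WEC
draw-by-draw.  Negative ADC (uncontrolled input already exceeds capacity)
is reported with a warning, never clamped — it is decision-relevant.
Period-over-period emission reductions are `1 − ADC_next/ADC_prev`, with
the first period anchored at a fixed baseline emission.

Known reconciliation limit: published 2010→2015 ADC-reduction ranges for
Taihu (49–54% TN, 60–71% TP) cannot be reproduced from the printed `W`,
`α`, baseline emissions and the 2011 capacity table alone; the original
planning tables evidently used additional unpublished inputs.  The package
therefore reports its own internally consistent transition ratios and
asserts nothing about those ranges.

## Synthetic data

`simulate_series` draws annual loads and outflows as lognormals
(positive, right-skewed, as hydrological records are), pushes them through
the steady-state model (or steps the transient solution year by year) at a
known `true_s`, and adds Gaussian noise on the canonical concentration
scale, truncated at zero.  Truncations are counted and warned about: the
inference assumes untruncated noise, so designs should keep `true_sigma`
small enough that truncation is negligible (at the defaults it never
occurs).

Default design (chosen once, to match the magnitudes of the Taihu record):
24 years; V = 44.3; load mean 5 × 10^4 t/a with CV 0.3; outflow mean
135.9 × 10^8 m^3/a with CV 0.25, giving a mean flushing rate near 3.07/a
(the value implied jointly by the published posterior means and capacity
table); `true_s` = 1.861/a; `true_sigma` = 20 t per 10^8 m^3 (0.2 mg/L,
the residual scatter scale implied by the published posterior SD).  With
these settings synthetic TN concentrations fall in the observed 1–5 mg/L
range and the fitted posterior SD (~0.08/a) matches the published one —
i.e. the synthetic regime stresses the same numerical ranges as the real
inverse problem.

What the generator does *not* emulate: serial correlation between years,
trends in loading, measurement error in I and Q themselves, seasonal
structure, or the actual historical Taihu trajectory.  Passing recovery
tests therefore demonstrate correctness of the inference machinery under
its own assumptions, not robustness to their violation.

`recovery_experiment` repeats simulate → fit → summarise at a fixed truth
and reports 5–95% interval coverage (nominal 90%) and mean bias.  The
validation replicates use shortened 6,000-iteration chains (1,500
burn-in): with an effective sample size in the thousands for a
two-parameter posterior, quantile noise is far below the posterior width,
and chain length per replicate is a numerical choice of the harness, not
part of the inference defaults.

## Numerical choices and edge cases

- Units: all internal arithmetic in t, 10^8 m^3 and years; mg/L only at
  I/O boundaries (×100).  The round-trip is exact to 1 ulp (a binary
  float cannot survive ×100/÷100 bit-exactly).
- `Q = 0` (closed lake) is allowed whenever `S > 0`; `r + S ≤ 0` is
  rejected (no steady state).
- Degenerate chains (zero variance) are rejected by `summarize_posterior`
  with a dedicated error, and fail the convergence check.
- Chains shorter than 100 draws are refused a summary; batch-means MC
  error truncates the oldest draws when the length is not divisible by 50.
- The convergence threshold is a strict inequality (ratio exactly 0.08
  fails).
- Reduction ratios may be negative (capacity exceeds load): reported
  as-is, meaning no reduction is required.

## Limitations

Annual averaging hides seasonal bloom dynamics; the steady-state
likelihood assumes each year is near equilibrium (reasonable when
`1/(r+S)` ≈ 0.2 a, as for Taihu, but not for slowly flushed lakes); `W`
and `α` are treated as known constants though they are themselves
estimates; and the published capacity tables can only be reproduced to
the precision of their printed, rounded entries (integer t/a capacities
propagate to ~0.015 percentage points in reduction ratios and tens of
t/a in cross-nutrient capacity predictions).
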
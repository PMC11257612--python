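# chemoinfo

How close does *E. coli* chemosensing come to the physical limit set by the
stochastic arrival of ligand molecules at its receptors?  `chemoinfo`
implements the full comparison as a tested, reproducible pipeline for
systems-biology and biophysics researchers: forward models of chemotactic
signals, molecule arrivals and CheA kinase activity; exact causal-filtering
information rates for both channels; synthetic versions of the three
calibration experiments (swimming tracks, FRET step responses, FRET noise
recordings) with the parameter-estimation chain that analyzes them; and
run-tumble agent simulations that connect information rates to
gradient-climbing speed.

## The model in brief

In a static exponential gradient of steepness `g = d(log c)/dx`, the
behaviorally-relevant signal is `s(t) = g·vx(t)`, Gaussian with
autocovariance `g²σv² exp(−|u|/τv)`.  Two observers estimate `s(t)`
causally:

* an **ideal sensor** sees molecule arrivals, rate `r(t) = k_D c(t)` with
  `k_D = 4Dl ≈ 1.2×10⁵ s⁻¹µM⁻¹`, Gaussianized as
  `(r−r0)/r0 = log(c/c0) + ξ/√r0`;
* the **cell** sees its kinase activity
  `a(t) = a0 − ∫K_r(t−t′)(r(t′)−r0)dt′ + η(t)`, with an adaptive kernel
  `K_r(t) = G_r[(1/τ1)e^{−t/τ1} − (1/τ2)e^{−t/τ2}]` and slow internal noise
  `⟨η(t)η(t′)⟩ = D_n τ_n e^{−|t−t′|/τ_n}`.

Sensing accuracy is the transfer-entropy (equivalently predictive-
information) rate, which for these Gaussian channels is
`İ = (1/τv)·ρ²/(1−ρ²)` with `ρ²` the squared correlation between `s` and
its optimal causal estimate — computed here by a correlated-noise algebraic
Riccati solver and cross-checked against an independent Wiener–Hopf
spectral-factorization route.  The headline quantities are the SNRs
`γ_r = 2r0g²σv²τv³` and `γ_a = (G_r²/D_n)r0²g²σv²τv`, and the efficiency
`η = İ_a/İ_r`.

## Worked example

```python
from chemoinfo import load_published, gamma_r, efficiency_eta
from chemoinfo.information import solve_physical_limit_filter, solve_kinase_filter

swim, kin, env = load_published(c0=1.0)   # population medians at 1 uM

g = 0.05e-3                               # 0.05 mm^-1, in um^-1
print(gamma_r(env, swim, g))              # 0.14761992840000002
print(efficiency_eta(env, swim, kin, 0))  # 0.014214931700462893  (g -> 0+)
print(efficiency_eta(env, swim, kin, 0.4e-3))  # 0.1205951549244105

sol = solve_physical_limit_filter(env, swim, g)
print(sol.rho2, sol.info_rate)            # 0.020040749... 0.017185373... nats/s
```

The first number says molecule arrivals carry a signal-to-noise of only
0.15 in a typical shallow gradient — far below the classic single-run
counting threshold of 16/3, yet simulated cells still climb.  The second
and third say a typical cell encodes only ~1.4% of the physically available
information about the signal in a vanishing gradient at the best measured
background, rising to ~12% (the reported “≈0.1”) in the steepest gradient
analyzed — not because the cell improves, but because the physical limit
saturates.

The same comparison as tables:

```bash
chemoinfo info-rates --sweep --out comparison_tables/
```

## Analysis scripts

The `analysis/` drivers narrate the full study on synthetic data and write
their outputs under `results/`:

1. `01_simulate_experiments.py` — generate the three calibration
   experiments at the published medians (tracks, step responses, noise
   traces);
2. `02_fit_parameters.py` — run the estimation pipeline on them and compare
   recovered medians with the generation values;
3. `03_information_rates.py` — the information-rate comparison tables and
   noise-PSD decomposition;
4. `04_chemotaxis_drift.py` — ideal vs *E. coli*-like agents across
   gradients and the `va/vr = √(İa/İr)` check.

A `chemoinfo` CLI exposes the same stages (`synthesize`, `fit`,
`info-rates`, `simulate`, `reproduce`).

## Layout

```
src/chemoinfo/        models, information, synthetic, estimation,
                      chemotaxis, pipeline, params, cli
analysis/             numbered narrative drivers
tests/                pytest suite (unit, property and acceptance tests)
docs/methods.md       modeling and numerical choices, in detail
```
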
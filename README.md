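# noisygrowth

Noise-driven clonal growth models with finite-memory (colored) growth-rate
noise: exact simulators, closed-form time-dependent population distributions,
growth-rate statistics, and a fitness/survivability layer for selection-sweep
experiments.

The package implements and cross-validates two population models driven by a
stationary Ornstein–Uhlenbeck growth rate `g_c` with autocovariance
`D·exp(-Δt/τ_c)`:

* **linear multiplicative growth** `dC/dt = (γ + g_c) C` — log-normal
  population law with time-varying growth exponent `α(t) → D·τ_c`;
* **stochastic logistic self-regulation** `dC/dt = γC − (ε + g_c) C²` —
  mapped truncated-Gaussian law with carrying capacity `C* = γ/ε`, plus the
  full coupled growth-input system it reduces from.

Every closed form ships with an independent numerical oracle (nested
quadrature, exact one-sample Kolmogorov–Smirnov validation against simulated
ensembles) and the selection layer turns a fitness function `f(C) ∈ [0,1]`
into survivability coefficients `S = ∫ f·P dC`, iterated selection sweeps
with noise memory carried across rounds, and exhaustive parameter-grid
optimization.

## Command line

All functionality is exposed through a `noisygrowth` command with
subcommands `simulate-linear`, `simulate-logistic`, `simulate-coupled`,
`analytic-pdf`, `moments`, `chi`, `survivability`, `iterate-selection`,
`optimize`, `validate`, and `noise-diagnose`. Examples:

```bash
# closed-form mean/dispersion table for the linear model
noisygrowth moments --model linear --tau-c 1 --d 1 --t 0:4:0.4 --out moments

# KS-validate the simulator against the closed-form law (exits nonzero on failure)
noisygrowth validate --model linear --tau-c 0.01 --d 100 \
    --t 0.05,0.15,0.25 --n 10000 --seed 1 --out validation

# noise diagnostics: autocovariance fit + sign-process Markov decomposition
noisygrowth noise-diagnose --tau-c 1 --d 1 --t 0:100:0.1 --n 1000 --out diag
```

Time/value grids accept `start:stop:step` or comma lists. Every subcommand
accepts `--config FILE` (flat `key = value` lines mirroring the flags;
explicit flags win) and writes a `<out>.manifest.json` recording command,
parameters, seed and package version; re-running a manifest's command
reproduces its outputs byte-identically. Ensembles are written as CSV (one
column per replicate) with a JSON parameter sidecar; tables as TSV.

## Package layout

| module | contents |
| --- | --- |
| `noisygrowth.colored_noise` | OU noise sampling (exact discretization), autocovariance estimation, `(D, τ_c)` recovery, two-state sign-process Markov decomposition |
| `noisygrowth.sde_models` | ensemble simulators (exact linear sampling; adaptive-Heun logistic and coupled integrators with divergence capping), histograms |
| `noisygrowth.analytic_solutions` | closed-form PDFs, moments, β(t), growth-rate statistics χ, limit reports |
| `noisygrowth.selection` | fitness functions, survivability, iterated selection, grid optimization |
| `noisygrowth.validation` | simulation-vs-closed-form KS harness |
| `noisygrowth.cli` | command-line front end, config files, run manifests |
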
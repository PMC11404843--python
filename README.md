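# carlsim

Simulation and analysis of **collective asymmetric reinforcement learning**:
groups of Q-learning agents solve a static two-armed bandit with ±1 payoffs
while observing every other agent's actions and outcomes. Each agent updates
*confirmatory* information (rewards on its chosen arm, penalties on the
unchosen arm) with learning rate α⁺ and *disconfirmatory* information with
α⁻; the ratio b = α⁺/α⁻ is the bias strength. The package provides:

- `carlsim.environment` — the two-armed ±1 bandit and the poor / mixed /
  rich scarcity presets (p₁/p₂ = 0.3/0.1, 0.6/0.4, 0.9/0.7), plus the
  analytic random-policy baseline p₁ + p₂ − 1.
- `carlsim.agents` — softmax policy, confirmatory/disconfirmatory feedback
  partition, the asymmetric collective update rule, and bias-strength
  schemes (`fixed_sum`: α⁺+α⁻ = 0.2; `fixed_minus`: α⁻ = 0.1, α⁺ = b·α⁻;
  `explicit` rate pairs).
- `carlsim.simulation` — a vectorized, seed-deterministic batch engine
  (1000 replicates × 1000 trials in under a second per cell) plus tidy
  parameter sweeps.
- `carlsim.deterministic` — the two-agent expected-update model for
  noise-free trajectories, fixed points, and perturbation/stability probes.
- `carlsim.analysis` — performance and performance improvement, final
  Q-value gaps, behavior profiles, KDE peak/regime detection, polarization
  (difference-of-gap) distributions, payoff-curve crossing points, and
  optimal-bias extraction.
- `carlsim.config` / `carlsim.cli` — YAML/JSON configs, named experiment
  grids, and CSV/JSON result I/O.

## CLI

```sh
carlsim presets                      # list scarcity + experiment presets
carlsim run --config cfg.yaml --out out/
carlsim sweep --experiment fig1_bias_strength --out out/ --seed 1
carlsim deterministic --preset rich --b 3 --steps 500 --perturb 1e-3 --out traj.csv
carlsim analyze --results out/fig2.csv --what peaks --out peaks.csv
```

A minimal config:

```yaml
preset: rich          # or task: [0.9, 0.7]
n: 5
bias: {scheme: fixed_sum, b: 3}   # or {alpha_plus: 0.17, alpha_minus: 0.03}
trials: 200
n_sims: 500
seed: 1
```

`beta` defaults to 4 everywhere. Sweep output is one tidy row per
(cell, replicate) with mean payoff, focal-agent payoff, and the focal and
second agents' final Q-value gaps; `analyze` turns these tables into
performance summaries, gap statistics, KDE peak tables, polarization peak
tables, or per-cell optimal bias strengths.

## Notes

- Replicate k of a batch uses child k of `numpy.random.SeedSequence(seed)`;
  results are bit-reproducible and independent of batch composition.
- The deterministic two-agent model applies the same 1/n (= 1/2) scaling as
  the stochastic rule, so a one-step increment equals the Monte-Carlo
  expected one-trial update (the tests verify this against a 10⁵-draw
  frozen-policy oracle).
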
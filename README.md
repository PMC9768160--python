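# satnet

An event-driven simulator of a recurrent attractor network with binary
neurons that computes two-alternative decisions, together with the
simulation experiments and statistics used to study how the brain
implements the **speed–accuracy tradeoff** (SAT): by moving the decision
threshold, by changing the evidence, or by modulating the excitability
("gain") of the choice circuit — and how **alpha oscillations** (8–12 Hz)
interfere with the decision process.

It is written for computational neuroscientists who want to reproduce,
probe or extend this class of winner-take-all decision models from
Python.

## The model

`N = 1000` excitatory binary neurons carry state `s(j) = 1` while
refractory (duration `1/τ₁ ≈ 14.3 ms`, capping single-neuron rates at
70 Hz).  Two decision pools A and B of `n = 100` neurons are more densely
connected within themselves (`d₁ = 0.55`) than the rest of the network
(`d₂ = 0.36`); connections are random, directed and binary.  Global
inhibition enters as a common activation threshold: when neuron `j` is
updated at time `t` it spikes iff

```
(Σᵢ s_t(i) w_ij + ext_j) / Σᵢ w_ij  >  (1/Θ) · (Σᵢ s_t(i) / N)²
```

with inhibition constant `Θ = 0.13`.  Updates are asynchronous: each
neuron carries an exponential update clock of rate `τ₂ = 0.006 ms⁻¹`,
except that after a spike the next evaluation falls exactly at
refractory expiry.  Evidence arrives as Poisson spike counts
(`λ_A`, `λ_B` per 30-ms window, `λ₀ = 15`) delivered to half of each
pool; stimulus strength maps linearly onto the rates (contrast mode
`λ_A = λ₀(½ + c)`, coherence mode `λ_A = λ₀(1 + c)/2`).  The decision
variable is the population-average rate of the winning pool (30-ms
windows sampled every 10 ms) against a threshold; alpha oscillations
modulate the inhibition constant as `Θ(t) = Θ₀ + α·sin(2πft + ξ)`.

The network has three semi-stable attractors — a spontaneous state
(pool rate ≈ 10.3 Hz), and two decision states (winner ≈ 59.7 Hz, loser
≈ 2 Hz) — and performs noisy evidence integration from the first to one
of the latter.

## Worked example

```
$ python examples/01_single_trial.py
choice: A
reaction time: 730 ms
baseline rate (pre-stimulus): 9.7 Hz
spikes recorded: 16501
pool rates at crossing: A=52.3 Hz, B=24.7 Hz
```

The network rested near 10 Hz for 1 s, then Poisson evidence at contrast
8.21% ramped pool A across the 50-Hz threshold 730 ms after stimulus
onset while pool B was being suppressed — a single simulated decision
with a realistic reaction time.  The other example scripts measure the
attractor states, fit the dot-motion psychometric function (Weibull
threshold `α ≈ 12.5`% coherence), contrast threshold- versus
gain-mediated SAT (only the former yields faster errors than correct
responses), and map the non-monotonic effect of alpha amplitude on
accuracy.

A thin command-line interface wraps the same machinery:

```
satnet simulate-trial --config cfg.yaml --seed 1 --out run/
satnet run-experiment --spec exp.yaml --scale 0.1 --seed 1 --out out/
satnet summarize --table out/trials.csv --out summary.csv
satnet selftest
```

## Library layout

- `satnet.network` — connectivity generation, state initialization, the
  global-inhibition update rule
- `satnet.engine` — stimulus drives, alpha modulation, the event-driven
  trial loop (numba kernel in `satnet._kernel`, naive cross-checking
  reference in `satnet._reference`)
- `satnet.metrics` — pool rates, decision detection, attractor-state
  classification, baseline rate, integration speed
- `satnet.experiments` — the five study drivers (dot motion, threshold
  sweep, input-space Monte Carlo, gain sweep, alpha study) and exclusion
  rules, producing tidy trial tables
- `satnet.stats` — d′, Weibull psychometric fits, OLS with bootstrap
  CIs, probit regression, RT summaries, the input-space neighborhood map
- `satnet.io` / `satnet.cli` — YAML configs, checksummed run manifests,
  the CLI
- `satnet.validation` — the headline-quantity reproductions used below

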
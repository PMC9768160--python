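# Methods

## Model

The decision circuit is a recurrent network of `N = 1000` binary
excitatory neurons with two evidence-selective pools A and B of
`n = 100` neurons each.  A neuron's binary state marks its refractory
status: `s(j) = 1` from a spike until `1/τ₁` later (`τ₁ = 0.07 ms⁻¹`,
i.e. 14.286 ms, which caps single-neuron rates at 70 Hz and doubles as
the synaptic integration window, so the recurrent input to `j` is the
number of its presynaptic neurons that spiked within the last
`1/τ₁`).  Connections `w_ij ∈ {0, 1}` are random, directed and
non-symmetric, drawn independently per ordered pair with probability
`d₁ = 0.55` within a pool and `d₂ = 0.36` elsewhere, no
self-connections; connectivity is regenerated before every trial (a
flag can freeze it).

Global inhibition is a common activation threshold that scales with the
square of the fraction of active neurons.  An update of non-refractory
neuron `j` at time `t` emits a spike iff

    (Σᵢ s_t(i) w_ij + ext_j(t)) / Σᵢ w_ij  >  (1/Θ(t)) · (Σᵢ s_t(i)/N)²

strictly; ties do not fire, and a neuron with zero in-degree never fires
(the 0/0 case; at the default densities such neurons essentially never
occur).  `Θ = 0.13` by default; its admissible domain (0.1, 0.2) is tied
to the 10% pool fraction — below 0.1 a full pool cannot be
simultaneously active, above 0.2 both pools can be, breaking
winner-take-all.  External evidence `ext_j` enters the numerator only:
input spikes add to the postsynaptic count but the rule normalizes by
the recurrent in-degree.

## Asynchronous scheduling

The printed description — exponential inter-update intervals with rate
`τ₂ = 0.006`, "except for the constant refractory periods" — admits
several readings, and the choice dominates every emergent number.  This
implementation treats `τ₂` as the **per-neuron update rate in ms⁻¹**
(mean inter-update interval `1/τ₂ ≈ 166.7 ms`, structurally parallel to
`τ₁ = 0.07 ↦ 14.3 ms`), realized as the equivalent global Poisson
stream of rate `N·τ₂ = 6` events/ms that selects a neuron uniformly at
each event.  The refractory clause is read as: after a spike the
neuron's next evaluation falls **exactly at refractory expiry**
(`update_at_expiry=True`).  Three facts force this combination:

- a sustained decision-state rate of ~60 Hz requires re-evaluation
  every ~15–17 ms for active neurons, which only expiry-triggered
  updates provide (any purely exponential schedule consistent with the
  printed `τ₂` caps sustained rates far lower);
- the resulting spontaneous state sits at 10–11 Hz (published
  10.3 Hz) and reaction times at strong evidence come out near 400 ms
  (published: hundreds of ms) — the faster readings we tested produced
  16 Hz and ~40 ms;
- the baseline-rate-vs-alpha-amplitude slope reproduces the published
  −14.6 Hz per unit amplitude to within a few percent with nothing
  fitted.

Per-neuron independent exponential clocks and the global uniform-marked
stream are the same point process (superposition), so no separate
scheduling variant is exposed; `update_at_expiry` is the one switch.

## Event loop

The kernel (numba) keeps the network activity count and each neuron's
active-presynaptic count incrementally: an evaluation is O(1), a spike
or expiry is O(out-degree).  Refractory expiries live in a FIFO ring
buffer (the refractory period is constant, so insertion order is time
order); expiries due before the next random event are processed first,
each expiry evaluating its neuron at its exact expiry instant.  The
activity test is `last_spike + 1/τ₁ > t`, written in that float form so
the expiry instant classifies identically in the queue and in the naive
reference implementation that validates the kernel spike-for-spike on
small networks.

All randomness is pre-drawn per trial from one PCG64 generator in a
fixed order (connectivity, initial state, event stream, neuron marks,
per-window Poisson counts, tie-break coin), making trials bit-for-bit
reproducible from a single integer seed; experiment drivers derive
per-trial seeds from (master seed, cell id, trial index) so any table
row can be re-simulated in isolation.

**Initial refractory phases.** The network initializes each neuron
active with probability Θ.  Initially active neurons draw a refractory
phase uniformly over the refractory period (entry time in `(-1/τ₁, 0]`)
rather than sharing entry time 0: under the rule's instant semantics,
co-expiring neurons are mutually invisible at their common expiry, and a
simultaneous cohort of ~130 neurons then refires as a permanently
phase-locked assembly that inflates the spontaneous rate to ~17 Hz and
triples its variance.  With staggered phases no two spikes ever share a
timestamp (almost surely) and the artifact cannot arise.  This is the
stationary-entry assumption; it is an initialization choice, not a
dynamical one.

## Stimulus, readout and trial protocol

Poisson means are resampled once per 30-ms window per pool and the same
count is delivered to every targeted neuron (half of each pool, chosen
per trial); a constant-input mode substitutes the real-valued means.  A
trial runs 1000 ms of spontaneous activity, then the stimulus, and
evaluates the decision variable only after onset: pool rates over
trailing 30-ms windows sampled every 10 ms, first strict crossing of the
threshold wins, reaction time measured from onset at 10-ms resolution.
If both pools cross at one grid point the higher rate wins (residual
exact ties: fair coin).  No-decision trials are those with no crossing
by the deadline (2000 ms in the SAT experiments, 2500 ms in the alpha
study; dot-motion stimulus epoch 2 s).  Alpha modulation
`Θ(t) = Θ₀ + α sin(2πft/1000 + ξ)` (t in ms) applies from `t = 0`,
including the pre-stimulus epoch.

The experiment drivers reproduce the five studies: dot motion
(coherences 0–51.2%, threshold 52.5 Hz), threshold sweep (contrasts
4.98–13.53%, readout thresholds 20–50 Hz evaluated post hoc on the same
simulated activity, which pairs the threshold comparison trial by
trial), input-space Monte Carlo (`λ_A, λ_B ~ U(0, 20)²`), gain sweep
(`Θ ~ U(0.1, 0.2)`), and the alpha study (amplitude 0–0.1, frequency
8–12 Hz, random phase).  Exclusion rules (no-decision, RT > 2000 ms,
RT < 100 ms) flag rather than delete rows; the RT-difference analyses
keep fast decisions, mirroring how each published panel treats them.

## Statistics

d′ clamps proportions to `[1/(2n), 1 − 1/(2n)]` before the normal
quantiles.  The Weibull psychometric `1 − ½·exp(−(c/α)^β)` is fitted by
unweighted least squares on per-level proportions (binomial weighting
available); the zero-strength point predicts 0.5 identically and so
cannot influence the parameters.  OLS slopes carry closed-form t
statistics plus a percentile case-resampling bootstrap (default
B = 10 000).  Probit regressions are maximum likelihood with an
intercept; separation is detected and reported.  Skewness is the biased
moment estimator `g₁ = m₃/m₂^{3/2}`.  The input-space neighborhood map
grows square neighborhoods (step 0.05, max half-width ±2.5) around
random probes until ≥ 50 erroneous decisions are inside, dropping probes
that never reach the quota.

## Desk-scale reproduction and its tolerances

`scripts/acceptance.py` and the reproduction tests use hundreds of
trials per condition (vs. thousands in the study): spontaneous state
from 20 five-second runs, decision state from ~24 driven trials, the Θ
regression from ~500–600 trials, each alpha condition from ~300–320,
dot motion from 300 per coherence level.  Monte-Carlo error at these
sizes is roughly 1–2 percentage points on accuracies, ±0.3–0.5 Hz on
attractor rates and ~8% on regression slopes, which the test tolerances
reflect.  Attractor-state rates are measured while the network occupies
the state in question (winner ≥ 50 Hz and loser ≤ 20 Hz sustained
100 ms for decision states; spontaneous windows truncated at a
committed escape), since the published numbers describe the states
themselves, not mixtures with transition periods.

## Known limitations

- The spontaneous state is somewhat more volatile than published:
  30-ms-window pool-rate SD ≈ 7 Hz against 5.2, with transient
  excursions above 50 Hz occupying a few percent of time.  This shows
  up as a slightly high exclusion fraction in dot motion (≈ 2–3% vs
  2.5% published, dominated by sub-100-ms crossings from fluctuation
  peaks present at onset).
- The decision attractor sits 2–7% below the published 59.7 Hz.  The
  visible consequence: under deep inhibition troughs (alpha amplitudes
  0.08–0.1) marginal 50-Hz crossings fail more often, and the
  no-decision fraction at contrast 8.21% measures ≈ 45–51% against the
  published 39% — the one headline number this implementation misses.
  Every neighboring statistic (accuracy with and without alpha, the
  amplitude regressions) matches, which localizes the gap to the
  attractor's exact height rather than the alpha coupling.
- The integration-speed-vs-Θ regression reproduces the published sign
  but attenuated (≈ −2 to −4 vs −13.5 Hz/100 ms per unit Θ at desk
  scale, CI half-width ≈ 9); integration speed is the noisiest
  per-trial metric here.
- Synthetic inputs only: the generator emulates stationary Poisson
  evidence with a linear stimulus mapping.  Real sensory drives are
  non-stationary and correlated, so passing these checks validates the
  circuit model and pipeline, not any claim about biological input
  statistics.  Learning, explicit inhibitory populations,
  collapsing-bound readouts and time-varying alpha amplitude are out of
  scope.
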
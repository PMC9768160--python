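"""Trial-level simulation: stimulus drives, alpha modulation, and the event loop.

A trial consists of ``pre_ms`` of spontaneous run, stimulus onset, and a
decision epoch during which the population-average firing rate of each
decision pool (30-ms trailing windows sampled every 10 ms) is compared
against a threshold.  The first pool whose rate strictly exceeds the
threshold wins; reaction time is measured from stimulus onset.  If
neither pool crosses before the deadline the trial ends with no decision
(the network typically remains in the spontaneous state).

Evidence enters as per-window Poisson counts delivered to half of each
decision pool, resampled every 30 ms.  Alpha oscillations are modeled as
a sinusoidal modulation of the inhibition constant,
``Theta(t) = Theta0 + amplitude * sin(2*pi*f*t/1000 + phase)``, applied
throughout the whole run including the pre-stimulus epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import _kernel
from .network import ConnectionMatrix, NetworkConfig, generate_connectivity, initialize_state

__all__ = [
    "StimulusDrive",
    "AlphaModulation",
    "TrialProtocol",
    "TrialResult",
    "theta_at",
    "map_stimulus",
    "sample_input_counts",
    "run_trial",
]


@dataclass(frozen=True)
class StimulusDrive:
    """External evidence drive to the two decision pools.

    ``mode`` selects how stimulus strength ``c`` (a fraction, e.g.
    0.0821 for 8.21%) maps to the two per-window Poisson means:

    * ``contrast``:  lambda_A = lambda0 * (1/2 + c), lambda_B = lambda0 * (1/2 - c)
    * ``coherence``: lambda_A = lambda0 * (1 + c)/2, lambda_B = lambda0 * (1 - c)/2
    * ``raw``:       lambda_A, lambda_B given directly.

    With ``input_style="constant"`` the real-valued means themselves are
    delivered each window instead of Poisson draws.
    """

    mode: Literal["contrast", "coherence", "raw"] = "coherence"
    c: float = 0.0
    lambda0: float = 15.0
    lambda_A: float | None = None
    lambda_B: float | None = None
    window_ms: float = 30.0
    duration_ms: float | None = None  # None: stimulus stays on until the trial ends
    input_style: Literal["poisson", "constant"] = "poisson"

    def __post_init__(self) -> None:
        if self.mode != "raw" and self.c < 0:
            raise ValueError("stimulus strength c must be non-negative")
        la, lb = self.rates()
        if la < 0 or lb < 0:
            raise ValueError(f"negative Poisson mean: lambda_A={la}, lambda_B={lb}")

    def rates(self) -> tuple[float, float]:
        if self.mode == "raw":
            if self.lambda_A is None or self.lambda_B is None:
                raise ValueError("raw mode requires explicit lambda_A and lambda_B")
            return float(self.lambda_A), float(self.lambda_B)
        return map_stimulus(self.mode, self.c, self.lambda0)


@dataclass(frozen=True)
class AlphaModulation:
    """Sinusoidal modulation of the inhibition constant by alpha oscillations.

    ``Theta(t) = Theta0 + amplitude * sin(2*pi*frequency_hz*t/1000 + phase)``.
    Amplitudes up to 0.1 keep Theta positive at the default Theta0=0.13
    (the constant then swings between 0.03 and 0.23).
    """

    amplitude: float = 0.0
    frequency_hz: float = 10.0
    phase: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude <= 0.1):
            raise ValueError("alpha amplitude must lie in [0, 0.1]")
        if self.enabled and self.amplitude > 0 and not (8.0 <= self.frequency_hz <= 12.0):
            raise ValueError("alpha frequency must lie in the 8-12 Hz band")

    @property
    def omega(self) -> float:
        """Angular frequency in radians per millisecond."""
        return 2.0 * math.pi * self.frequency_hz / 1000.0


@dataclass(frozen=True)
class TrialProtocol:
    """Timing and decision-readout parameters of a trial."""

    pre_ms: float = 1000.0
    max_decision_ms: float = 2000.0
    decision_threshold_hz: float = 50.0
    rate_window_ms: float = 30.0
    rate_step_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.pre_ms < 0:
            raise ValueError("pre_ms must be non-negative")
        if self.max_decision_ms <= 0:
            raise ValueError("max_decision_ms must be positive")
        if self.rate_window_ms <= 0 or self.rate_step_ms <= 0:
            raise ValueError("rate window and step must be positive")


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    choice: Literal["A", "B", "none"]
    rt_ms: float | None
    times: np.ndarray  # 10-ms evaluation grid (ms, from trial start)
    rates_A: np.ndarray  # pool-A population rate (Hz), 30-ms trailing windows
    rates_B: np.ndarray
    spike_log: tuple[np.ndarray, np.ndarray] | None  # (times_ms, neuron_ids)
    onset_ms: float
    condition: dict = field(default_factory=dict)

    @property
    def decided(self) -> bool:
        return self.choice != "none"


def theta_at(t: float, mod: AlphaModulation | None, theta0: float = 0.13) -> float:
    """Effective inhibition constant at time ``t`` (ms)."""
    if mod is None or not mod.enabled or mod.amplitude == 0.0:
        return theta0
    return theta0 + mod.amplitude * math.sin(mod.omega * t + mod.phase)


def map_stimulus(mode: str, c: float, lambda0: float = 15.0) -> tuple[float, float]:
    """Map stimulus strength to the two per-window Poisson means."""
    if mode == "contrast":
        if c >= 0.5:
            raise ValueError("contrast mode requires c < 0.5")
        la, lb = lambda0 * (0.5 + c), lambda0 * (0.5 - c)
    elif mode == "coherence":
        if c > 1.0:
            raise ValueError("coherence mode requires c <= 1")
        la, lb = lambda0 * (1.0 + c) / 2.0, lambda0 * (1.0 - c) / 2.0
    else:
        raise ValueError(f"unknown stimulus mode {mode!r}")
    if la < 0 or lb < 0:
        raise ValueError("negative Poisson mean")
    return la, lb


def sample_input_counts(drive: StimulusDrive, window_index: int, rng: np.random.Generator) -> tuple[float, float]:
    """Draw the external input counts for one 30-ms window (one draw per pool)."""
    la, lb = drive.rates()
    if drive.input_style == "constant":
        return la, lb
    return float(rng.poisson(la)), float(rng.poisson(lb))


# ---------------------------------------------------------------------------
# stream pre-generation (consumption order is part of the trial contract:
# connectivity, initial state, event intervals, event neurons, window counts)
# ---------------------------------------------------------------------------

def draw_event_stream(
    rng: np.random.Generator, horizon_ms: float, tau2: float, N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-draw global update events covering ``horizon_ms``.

    Each neuron carries an independent exponential update clock of rate
    ``tau2`` per ms (mean inter-update interval 1/tau2 ~ 166.7 ms).  The
    superposition of the N clocks is a global Poisson process of rate
    ``N * tau2`` per ms whose events select a neuron uniformly, which is
    how the stream is drawn here.  The draw is padded so that running
    out before the horizon is a <1e-6 probability event; if it happens
    anyway the stream is extended with further draws from the same
    generator.
    """
    mean_interval = 1.0 / (N * tau2)
    expect = horizon_ms / mean_interval
    m = int(expect + 10.0 * math.sqrt(expect) + 64)
    times = np.cumsum(rng.exponential(mean_interval, size=m))
    neurons = rng.integers(0, N, size=m, dtype=np.int64).astype(np.int32)
    while times[-1] < horizon_ms:  # pragma: no cover - astronomically rare
        extra = int(expect * 0.1 + 64)
        t2 = times[-1] + np.cumsum(rng.exponential(mean_interval, size=extra))
        times = np.concatenate([times, t2])
        neurons = np.concatenate([neurons, rng.integers(0, N, size=extra, dtype=np.int64).astype(np.int32)])
    return times, neurons


def draw_window_counts(
    rng: np.random.Generator, drive: StimulusDrive | None, stim_span_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-draw the per-window external counts for both pools."""
    if drive is None or stim_span_ms <= 0:
        return np.zeros(0), np.zeros(0)
    n_windows = int(math.ceil(stim_span_ms / drive.window_ms))
    la, lb = drive.rates()
    if drive.input_style == "constant":
        return np.full(n_windows, la), np.full(n_windows, lb)
    counts_A = rng.poisson(la, size=n_windows).astype(np.float64)
    counts_B = rng.poisson(lb, size=n_windows).astype(np.float64)
    return counts_A, counts_B


def _target_and_pool_flags(conn: ConnectionMatrix) -> tuple[np.ndarray, np.ndarray]:
    N = conn.N
    target = np.zeros(N, dtype=np.int8)
    target[conn.input_targets_A] = 1
    target[conn.input_targets_B] = 2
    pool = np.zeros(N, dtype=np.int8)
    pool[conn.pool_A] = 1
    pool[conn.pool_B] = 2
    return target, pool


def run_trial(
    config: NetworkConfig,
    drive: StimulusDrive | None = None,
    mod: AlphaModulation | None = None,
    protocol: TrialProtocol | None = None,
    rng: np.random.Generator | int | None = None,
    conn: ConnectionMatrix | None = None,
    post_decision_ms: float = 0.0,
    detect: bool = True,
    keep_spikes: bool = True,
    condition: dict | None = None,
) -> TrialResult:
    """Simulate one trial of the decision network.

    Connectivity is regenerated from the trial RNG unless a frozen
    ``conn`` is supplied.  The trial runs ``protocol.pre_ms`` of
    spontaneous activity, switches the stimulus on, and evaluates the
    decision variable on the 10-ms grid; it terminates at the first
    threshold crossing (plus ``post_decision_ms`` of settling time, if
    requested) or at the deadline, in which case ``choice == "none"``.
    """
    if protocol is None:
        protocol = TrialProtocol()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    if conn is None:
        conn = generate_connectivity(config, rng)
    state0 = initialize_state(config, rng)

    onset = protocol.pre_ms
    deadline = onset + protocol.max_decision_ms
    horizon = deadline + (post_decision_ms if post_decision_ms > 0 else 0.0)

    if drive is not None:
        stim_span = drive.duration_ms if drive.duration_ms is not None else horizon - onset
        stim_onset = onset
        stim_offset = onset + stim_span
        window_ms = drive.window_ms
    else:
        stim_span, stim_onset, stim_offset, window_ms = 0.0, math.inf, math.inf, 30.0

    event_times, event_neurons = draw_event_stream(rng, horizon, config.tau2, config.N)
    counts_A, counts_B = draw_window_counts(rng, drive, stim_span)

    N = config.N
    refr = config.refractory_ms
    indptr, indices = conn.out_neighbors_csr()
    in_deg = conn.in_degrees()
    target_flag, pool_id = _target_and_pool_flags(conn)

    s = state0.s.copy()
    last_spike = state0.last_spike_time.copy()
    active_presyn = (s @ conn.weights).astype(np.int32)

    istate = _kernel.make_istate()
    istate[0] = int(s.sum())

    exp_time = np.empty(N + 1)
    exp_neuron = np.empty(N + 1, dtype=np.int32)
    init_active = np.flatnonzero(s)
    order = np.argsort(last_spike[init_active], kind="stable")
    init_sorted = init_active[order]
    exp_time[: init_sorted.size] = last_spike[init_sorted] + refr
    exp_neuron[: init_sorted.size] = init_sorted
    istate[3] = init_sorted.size  # ring tail (entries time-sorted)

    s_cap = int(N * horizon / refr) + N + 16
    spike_times = np.empty(s_cap)
    spike_neurons = np.empty(s_cap, dtype=np.int32)

    p_cap = int(config.n * horizon / refr) + config.n + 16
    poolA_t = np.empty(p_cap)
    poolB_t = np.empty(p_cap)
    n_pool_A = n_pool_B = 0

    step = protocol.rate_step_ms
    win = protocol.rate_window_ms
    thr = protocol.decision_threshold_hz
    n_grid = int(round(horizon / step))
    grid = step * np.arange(1, n_grid + 1)
    rates_A = np.zeros(n_grid)
    rates_B = np.zeros(n_grid)
    rate_denom = config.n * win / 1000.0  # spikes -> Hz per neuron

    theta_args = (0.0, 0.0, 0.0)
    if mod is not None and mod.enabled and mod.amplitude > 0:
        theta_args = (mod.amplitude, mod.omega, mod.phase)

    choice: str = "none"
    rt: float | None = None
    prev_spikes = 0
    stop_at = math.inf
    last_g = 0

    for gi in range(n_grid):
        g = grid[gi]
        status = _kernel.advance(
            istate, s, last_spike, active_presyn,
            indptr, indices, in_deg, target_flag, pool_id,
            exp_time, exp_neuron,
            event_times, event_neurons, counts_A, counts_B,
            refr, config.theta0, theta_args[0], theta_args[1], theta_args[2],
            stim_onset, stim_offset, window_ms,
            1 if config.update_at_expiry else 0,
            spike_times, spike_neurons, g,
        )
        if status != _kernel.OK:  # pragma: no cover - defensive
            raise RuntimeError(f"event kernel stopped with status {status}")
        n_sp = istate[4]
        if n_sp > prev_spikes:
            new_t = spike_times[prev_spikes:n_sp]
            new_p = pool_id[spike_neurons[prev_spikes:n_sp]]
            a_sel = new_t[new_p == 1]
            b_sel = new_t[new_p == 2]
            poolA_t[n_pool_A : n_pool_A + a_sel.size] = a_sel
            poolB_t[n_pool_B : n_pool_B + b_sel.size] = b_sel
            n_pool_A += a_sel.size
            n_pool_B += b_sel.size
            prev_spikes = n_sp

        lo = g - win
        a0 = np.searchsorted(poolA_t[:n_pool_A], lo, side="right")
        b0 = np.searchsorted(poolB_t[:n_pool_B], lo, side="right")
        ra = (n_pool_A - a0) / rate_denom
        rb = (n_pool_B - b0) / rate_denom
        rates_A[gi] = ra
        rates_B[gi] = rb
        last_g = gi

        if detect and choice == "none" and onset < g <= deadline:
            crossed_a = ra > thr
            crossed_b = rb > thr
            if crossed_a or crossed_b:
                if crossed_a and crossed_b:
                    if ra > rb:
                        choice = "A"
                    elif rb > ra:
                        choice = "B"
                    else:
                        choice = "A" if rng.random() < 0.5 else "B"
                else:
                    choice = "A" if crossed_a else "B"
                rt = g - onset
                if post_decision_ms > 0:
                    stop_at = g + post_decision_ms
                else:
                    break
        if detect and choice == "none" and g >= deadline and post_decision_ms > 0:
            break  # no decision: nothing to settle into
        if g >= stop_at:
            break

    end = last_g + 1
    spikes = None
    if keep_spikes:
        spikes = (spike_times[:prev_spikes].copy(), spike_neurons[:prev_spikes].copy())
    return TrialResult(
        choice=choice,
        rt_ms=rt,
        times=grid[:end],
        rates_A=rates_A[:end],
        rates_B=rates_B[:end],
        spike_log=spikes,
        onset_ms=onset,
        condition=dict(condition or {}),
    )
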
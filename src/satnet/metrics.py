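"""Measured quantities derived from spike logs: pool rates, decisions, states.

All rate readouts use population-average spike-count rates of a decision
pool over trailing windows: the rate at time ``t`` counts pool spikes in
``(t - window, t]`` divided by pool size and window length.  The
decision variable samples 30-ms windows every 10 ms; baseline-rate
analyses of alpha runs use 100-ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import TrialResult

__all__ = [
    "RateSeries",
    "pool_rate",
    "rate_series",
    "detect_decision",
    "classify_state",
    "integration_speed",
    "baseline_rate",
    "sustained_above",
    "decision_occupancy_mask",
]


@dataclass
class RateSeries:
    """Pool rates on the 10-ms evaluation grid."""

    times: np.ndarray
    rates_A: np.ndarray
    rates_B: np.ndarray

    @classmethod
    def from_trial(cls, trial: TrialResult) -> "RateSeries":
        return cls(trial.times, trial.rates_A, trial.rates_B)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times, self.rates_A, self.rates_B])
        np.savetxt(path, arr, delimiter=",", header="time_ms,rate_A_hz,rate_B_hz", comments="", fmt="%.6g")


def pool_rate(
    spike_log: tuple[np.ndarray, np.ndarray],
    pool: np.ndarray,
    t: float,
    window_ms: float = 30.0,
) -> float:
    """Population-average firing rate (Hz) of ``pool`` over ``(t - window, t]``.

    Defined as (spikes emitted by pool members in the window) divided by
    (pool size * window length in seconds).
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    pool = np.asarray(pool)
    if pool.size == 0:
        raise ValueError("empty pool")
    times, neurons = spike_log
    mask = (times > t - window_ms) & (times <= t) & np.isin(neurons, pool)
    return float(mask.sum()) / (pool.size * window_ms / 1000.0)


def rate_series(
    spike_log: tuple[np.ndarray, np.ndarray],
    pool_A: np.ndarray,
    pool_B: np.ndarray,
    horizon_ms: float,
    window_ms: float = 30.0,
    step_ms: float = 10.0,
) -> RateSeries:
    """Recompute both pools' trailing-window rate series from a spike log."""
    times, neurons = spike_log
    grid = step_ms * np.arange(1, int(round(horizon_ms / step_ms)) + 1)
    out = []
    for pool in (pool_A, pool_B):
        sel = np.isin(neurons, pool)
        st = np.sort(times[sel])
        hi = np.searchsorted(st, grid, side="right")
        lo = np.searchsorted(st, grid - window_ms, side="right")
        out.append((hi - lo) / (len(pool) * window_ms / 1000.0))
    return RateSeries(grid, out[0], out[1])


def detect_decision(
    series: RateSeries,
    threshold_hz: float,
    onset_ms: float,
    deadline_ms: float,
    rng: np.random.Generator | None = None,
) -> tuple[str, float | None]:
    """First strict threshold crossing by either pool after stimulus onset.

    Returns ``(choice, rt_ms)`` where rt is measured from onset, or
    ``("none", None)`` if neither pool crosses by the deadline.  If both
    pools cross at the same grid point the higher rate wins; an exact
    tie is broken by a fair coin from ``rng``.  Raising the threshold on
    a fixed series never shortens the RT.
    """
    if onset_ms >= deadline_ms:
        raise ValueError("onset must precede deadline")
    window = (series.times > onset_ms) & (series.times <= deadline_ms)
    idx = np.flatnonzero(window & ((series.rates_A > threshold_hz) | (series.rates_B > threshold_hz)))
    if idx.size == 0:
        return "none", None
    i = idx[0]
    ra, rb = series.rates_A[i], series.rates_B[i]
    if ra > threshold_hz and rb > threshold_hz:
        if ra == rb:
            if rng is None:
                rng = np.random.default_rng()
            choice = "A" if rng.random() < 0.5 else "B"
        else:
            choice = "A" if ra > rb else "B"
    else:
        choice = "A" if ra > threshold_hz else "B"
    return choice, float(series.times[i] - onset_ms)


# attractor-state rate bands (Hz): spontaneous 4-20 (we accept [0, 20]),
# decision winner >= 50, decision loser <= 20
SPONTANEOUS_BAND = (0.0, 20.0)
DECISION_FLOOR = 50.0
SUSTAIN_MS = 100.0


def classify_state(series: RateSeries, t: float) -> str:
    """Attractor-state label at grid time ``t``.

    ``decision_A``/``decision_B`` require the winning pool at or above
    50 Hz and the other at or below 20 Hz sustained over the preceding
    100 ms; ``spontaneous`` requires both pools inside the low band over
    the same span.  Transitional samples inherit the most recent stable
    label (``spontaneous`` if there is none yet).
    """
    grid = series.times
    if t < grid[0] or t > grid[-1]:
        raise ValueError(f"t={t} outside the series grid")
    label = "spontaneous"
    for ti in grid[grid <= t]:
        span = (grid > ti - SUSTAIN_MS) & (grid <= ti)
        ra, rb = series.rates_A[span], series.rates_B[span]
        if (ra >= DECISION_FLOOR).all() and (rb <= SPONTANEOUS_BAND[1]).all():
            label = "decision_A"
        elif (rb >= DECISION_FLOOR).all() and (ra <= SPONTANEOUS_BAND[1]).all():
            label = "decision_B"
        elif (ra <= SPONTANEOUS_BAND[1]).all() and (rb <= SPONTANEOUS_BAND[1]).all():
            label = "spontaneous"
        # otherwise transitional: keep the previous stable label
    return label


def integration_speed(
    series: RateSeries,
    onset_ms: float,
    crossing_ms: float,
    winner: str,
) -> float:
    """Ramping rate of the winning pool in Hz per 100 ms.

    (rate at the crossing - rate at onset) / (crossing - onset) * 100,
    with rates read from 30-ms windows on the series grid.
    """
    if crossing_ms <= onset_ms:
        raise ValueError("crossing must come after onset")
    rates = series.rates_A if winner == "A" else series.rates_B
    r0 = float(np.interp(onset_ms, series.times, rates))
    r1 = float(np.interp(crossing_ms, series.times, rates))
    return (r1 - r0) / (crossing_ms - onset_ms) * 100.0


def baseline_rate(
    trial: TrialResult,
    bin_ms: float | None = None,
) -> float:
    """Mean decision-set rate (both pools averaged) over the pre-stimulus epoch.

    With equal-width bins the mean over bins equals the epoch mean, so
    ``bin_ms`` only matters for variability analyses; it is accepted for
    interface symmetry with the 100-ms-bin alpha analyses.
    """
    pre = trial.times <= trial.onset_ms
    if not pre.any():
        raise ValueError("trial has no pre-stimulus epoch")
    return float((trial.rates_A[pre].mean() + trial.rates_B[pre].mean()) / 2.0)


def sustained_above(rates: np.ndarray, threshold_hz: float, sustain_samples: int = 10) -> int | None:
    """Index of the first grid point opening a run of ``sustain_samples``
    consecutive samples at or above ``threshold_hz``; None if none exists.

    Used to separate committed attractor transitions from transient
    fluctuation peaks (a 100-ms sustain at the 10-ms grid by default).
    """
    above = np.asarray(rates) >= threshold_hz
    run = 0
    for i, v in enumerate(above):
        run = run + 1 if v else 0
        if run >= sustain_samples:
            return i - sustain_samples + 1
    return None


def decision_occupancy_mask(
    winner_rates: np.ndarray,
    loser_rates: np.ndarray,
    sustain_samples: int = 10,
) -> np.ndarray:
    """Grid samples during which the network occupies a decision state.

    A sample is occupied when it belongs to a run of at least
    ``sustain_samples`` consecutive samples with the winning pool at or
    above 50 Hz and the losing pool at or below 20 Hz (the attractor
    bands used by :func:`classify_state`).
    """
    ok = (np.asarray(winner_rates) >= DECISION_FLOOR) & (np.asarray(loser_rates) <= SPONTANEOUS_BAND[1])
    out = np.zeros(ok.size, dtype=bool)
    run = 0
    for i, v in enumerate(ok):
        run = run + 1 if v else 0
        if run >= sustain_samples:
            out[i - sustain_samples + 1 : i + 1] = True
    return out
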
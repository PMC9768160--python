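"""Naive reference implementation of the event dynamics, for validation.

This module re-implements the asynchronous evolution directly from the
model's definition, with none of the incremental bookkeeping the fast
kernel relies on: at every evaluation the active-state vector, the
presynaptic sums and the network activity are recomputed from scratch
from spike times, and pending refractory expiries are kept in a plain
FIFO list.  It is O(N) per event and only usable for tiny networks, but
it consumes exactly the same pre-drawn random streams as the kernel, so
the two implementations must agree spike for spike.  The self-test
suite and the unit tests compare them on networks with N <= 30.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import AlphaModulation, StimulusDrive, theta_at
from .network import ConnectionMatrix, NetworkConfig

__all__ = ["simulate_reference"]


def simulate_reference(
    config: NetworkConfig,
    conn: ConnectionMatrix,
    initial_last_spike: np.ndarray,
    event_times: np.ndarray,
    event_neurons: np.ndarray,
    counts_A: np.ndarray,
    counts_B: np.ndarray,
    mod: AlphaModulation | None,
    stim_onset: float,
    stim_offset: float,
    window_ms: float,
    horizon_ms: float,
) -> list[tuple[float, int]]:
    """Replay a pre-drawn event stream and return the spike list.

    ``initial_last_spike`` is the per-neuron last-spike time at t = 0
    (-inf for initially inactive neurons; initial activations are not
    logged as spikes).
    """
    N = config.N
    R = config.refractory_ms
    W = np.asarray(conn.weights, dtype=np.int64)
    in_deg = W.sum(axis=0)
    target = np.zeros(N, dtype=int)
    target[conn.input_targets_A] = 1
    target[conn.input_targets_B] = 2

    last_spike = np.asarray(initial_last_spike, dtype=float).copy()
    # FIFO of (expiry_time, neuron); the constant R keeps it time-ordered
    init = np.flatnonzero(np.isfinite(last_spike))
    init = init[np.argsort(last_spike[init], kind="stable")]
    expiries: list[tuple[float, int]] = [(float(last_spike[j] + R), int(j)) for j in init]
    spikes: list[tuple[float, int]] = []

    def active_vector(t: float) -> np.ndarray:
        # refractory iff last_spike + R > t; written in this form (not
        # t - last < R) so the expiry instant last + R is classified
        # identically to the event queue, which stores that exact float
        return (last_spike + R > t).astype(np.int64)

    def evaluate(j: int, t: float) -> None:
        s = active_vector(t)
        if in_deg[j] == 0:
            return
        ext = 0.0
        if target[j] != 0 and stim_onset <= t < stim_offset:
            w = int((t - stim_onset) // window_ms)
            if w < len(counts_A):
                ext = counts_A[w] if target[j] == 1 else counts_B[w]
        lhs = (float(s @ W[:, j]) + ext) / in_deg[j]
        frac = s.sum() / N
        rhs = frac * frac / theta_at(t, mod, config.theta0)
        if lhs > rhs:
            last_spike[j] = t
            expiries.append((t + R, j))
            spikes.append((t, j))

    for te, jn in zip(event_times, event_neurons):
        if te > horizon_ms:
            break
        # refractory expiries due before this event
        while expiries and expiries[0][0] <= te:
            tx, jx = expiries.pop(0)
            # expiry itself clears the refractory state (t - last >= R)
            if config.update_at_expiry:
                evaluate(jx, tx)
        if active_vector(te)[jn] == 0:
            evaluate(int(jn), float(te))
    # drain expiries falling between the last processed event and the horizon
    while expiries and expiries[0][0] <= horizon_ms:
        tx, jx = expiries.pop(0)
        if config.update_at_expiry:
            evaluate(jx, tx)
    return spikes
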
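"""Event-driven core loop of the asynchronous binary-neuron simulator.

The network evolves as a global marked Poisson process (the
superposition of per-neuron exponential update clocks of rate ``tau2``
per ms): events arrive at rate ``N * tau2`` per ms and each evaluates
one neuron drawn uniformly from the whole network.  In addition, every
neuron is re-evaluated exactly when its refractory period expires; a
run of consecutive successful expiry evaluations therefore produces the
maximal single-neuron rate 1/tau1 (70 Hz at the default refractory
period of ~14.286 ms).

The loop keeps two incremental quantities so that a single evaluation
is O(1) and a spike (or expiry) is O(out-degree):

* ``active_total``        -- number of refractory neurons network-wide;
* ``active_presyn[j]``    -- number of active presynaptic neurons of j.

Refractory expiries live in a FIFO ring buffer: the refractory period is
a constant, so expiry times are processed in spike order.  Simultaneous
expiries (only possible among the initially activated neurons, which all
expire at 1/tau1) are processed in insertion order.

All randomness is consumed from pre-drawn arrays (event times, neuron
selections, per-window input counts), which makes trials exactly
reproducible and lets an independent reference implementation replay the
same draws event for event.
"""

import math

import numpy as np
from numba import njit

# status codes returned by advance()
OK = 0
EVENTS_EXHAUSTED = 1
SPIKE_BUFFER_FULL = 2


@njit(cache=True)
def advance(
    # mutable scalar state
    istate,  # int64[9]: active_total, ev_ptr, exp_head, exp_tail, n_spikes, nA, nB, status, _pad
    # network state
    s,  # uint8[N]
    last_spike,  # float64[N]
    active_presyn,  # int32[N]
    # structure
    indptr,  # int64[N+1]  out-neighbor CSR
    indices,  # int32[nnz]
    in_deg,  # int64[N]
    target_flag,  # int8[N]   0 none, 1 pool-A input target, 2 pool-B input target
    pool_id,  # int8[N]   0 other, 1 pool A, 2 pool B
    # refractory expiry ring buffer (capacity N+1)
    exp_time,  # float64[N+1]
    exp_neuron,  # int32[N+1]
    # pre-drawn randomness
    event_times,  # float64[M]  absolute times of global update events
    event_neurons,  # int32[M]
    counts_A,  # float64[W]  external drive per 30-ms window, pool-A targets
    counts_B,  # float64[W]
    # parameters
    refractory_ms,  # float64
    theta0,  # float64
    alpha_amp,  # float64 (0 disables modulation)
    alpha_omega,  # float64, rad per ms
    alpha_phase,  # float64
    stim_onset,  # float64 (inf if no stimulus)
    stim_offset,  # float64
    window_ms,  # float64
    update_at_expiry,  # bool-as-int64
    # output spike log
    spike_times,  # float64[S]
    spike_neurons,  # int32[S]
    t_end,  # float64: advance until all events with time <= t_end are processed
):
    N = s.shape[0]
    cap = exp_time.shape[0]
    n_windows = counts_A.shape[0]
    S = spike_times.shape[0]

    active_total = istate[0]
    ev_ptr = istate[1]
    head = istate[2]
    tail = istate[3]
    n_spikes = istate[4]
    nA = istate[5]
    nB = istate[6]
    status = OK
    batch = np.empty(N, dtype=np.int32)

    M = event_times.shape[0]
    while True:
        if ev_ptr >= M:
            status = EVENTS_EXHAUSTED
            break
        t_next = event_times[ev_ptr]
        bound = t_next if t_next <= t_end else t_end

        # drain refractory expiries due before the next processed instant;
        # entries sharing one expiry instant (the initially activated
        # cohort) are all deactivated before any of them is evaluated,
        # because s(j) = [t - last_spike(j) < 1/tau1] makes them
        # simultaneously inactive at that instant
        while head != tail and exp_time[head] <= bound:
            te = exp_time[head]
            nb = 0
            while head != tail and exp_time[head] == te:
                jn = exp_neuron[head]
                head = (head + 1) % cap
                s[jn] = 0
                active_total -= 1
                for k in range(indptr[jn], indptr[jn + 1]):
                    active_presyn[indices[k]] -= 1
                batch[nb] = jn
                nb += 1
            if update_at_expiry:
                for bi in range(nb):
                    jn = batch[bi]
                    ind = in_deg[jn]
                    if ind > 0:
                        ext = 0.0
                        if target_flag[jn] != 0 and stim_onset <= te < stim_offset:
                            w = int((te - stim_onset) / window_ms)
                            if w < n_windows:
                                ext = counts_A[w] if target_flag[jn] == 1 else counts_B[w]
                        th = theta0
                        if alpha_amp != 0.0:
                            th = theta0 + alpha_amp * math.sin(alpha_omega * te + alpha_phase)
                        frac = active_total / N
                        if (active_presyn[jn] + ext) / ind > frac * frac / th:
                            if n_spikes >= S:
                                status = SPIKE_BUFFER_FULL
                                break
                            s[jn] = 1
                            last_spike[jn] = te
                            active_total += 1
                            for k in range(indptr[jn], indptr[jn + 1]):
                                active_presyn[indices[k]] += 1
                            exp_time[tail] = te + refractory_ms
                            exp_neuron[tail] = jn
                            tail = (tail + 1) % cap
                            spike_times[n_spikes] = te
                            spike_neurons[n_spikes] = jn
                            n_spikes += 1
                            if pool_id[jn] == 1:
                                nA += 1
                            elif pool_id[jn] == 2:
                                nB += 1
            if status != OK:
                break
        if status != OK:
            break

        if t_next > t_end:
            break  # chunk complete; pending event stays for the next call

        jn = event_neurons[ev_ptr]
        ev_ptr += 1
        if s[jn] == 0:
            ind = in_deg[jn]
            if ind > 0:
                ext = 0.0
                if target_flag[jn] != 0 and stim_onset <= t_next < stim_offset:
                    w = int((t_next - stim_onset) / window_ms)
                    if w < n_windows:
                        ext = counts_A[w] if target_flag[jn] == 1 else counts_B[w]
                th = theta0
                if alpha_amp != 0.0:
                    th = theta0 + alpha_amp * math.sin(alpha_omega * t_next + alpha_phase)
                frac = active_total / N
                if (active_presyn[jn] + ext) / ind > frac * frac / th:
                    if n_spikes >= S:
                        status = SPIKE_BUFFER_FULL
                        break
                    s[jn] = 1
                    last_spike[jn] = t_next
                    active_total += 1
                    for k in range(indptr[jn], indptr[jn + 1]):
                        active_presyn[indices[k]] += 1
                    exp_time[tail] = t_next + refractory_ms
                    exp_neuron[tail] = jn
                    tail = (tail + 1) % cap
                    spike_times[n_spikes] = t_next
                    spike_neurons[n_spikes] = jn
                    n_spikes += 1
                    if pool_id[jn] == 1:
                        nA += 1
                    elif pool_id[jn] == 2:
                        nB += 1

    istate[0] = active_total
    istate[1] = ev_ptr
    istate[2] = head
    istate[3] = tail
    istate[4] = n_spikes
    istate[5] = nA
    istate[6] = nB
    istate[7] = status
    return status


def make_istate() -> np.ndarray:
    return np.zeros(9, dtype=np.int64)
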
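"""Static structure and single-neuron update rule of the binary-neuron attractor network.

The decision circuit is a recurrent network of ``N`` binary excitatory
neurons containing two decision pools, A and B, of ``n`` neurons each.
Connections are random, directed and binary, denser within each pool
(``d1``) than elsewhere (``d2``).  A neuron's state is 1 while it sits in
its refractory period and 0 otherwise; a spike is recorded every time an
update flips a neuron to 1.

Global inhibition is implemented through a common activation threshold
that grows with the square of the fraction of currently active neurons.
Neuron ``j`` fires on an update iff

    (sum_i s(i) w_ij + external) / (sum_i w_ij)  >  (1/Theta) * (sum_i s(i) / N)**2

with strict inequality.  ``Theta`` is the inhibition constant: larger
values lower the effective threshold and make neurons more excitable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

import numpy as np

__all__ = [
    "NetworkConfig",
    "ConnectionMatrix",
    "NetworkState",
    "generate_connectivity",
    "initialize_state",
    "evaluate_update",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and dynamical parameters of the decision network.

    Parameters
    ----------
    N : int
        Total number of neurons.
    n : int
        Neurons per decision pool (two disjoint pools).
    theta0 : float
        Inhibition constant Theta.  Values in (0.1, 0.2) preserve
        winner-take-all competition for pools of 10% of the network;
        the default 0.13 is the model's normative excitation level.
    tau1 : float
        Reciprocal of the refractory period in ms^-1.  1/tau1 ~ 14.286 ms
        caps the single-neuron firing rate at 70 Hz.
    tau2 : float
        Per-neuron update rate in ms^-1: each neuron is evaluated at
        exponentially distributed intervals of mean 1/tau2 (~166.7 ms),
        except that after a spike the next evaluation falls exactly at
        refractory expiry.  Network-wide, updates form a Poisson stream
        of rate N * tau2 per ms selecting neurons uniformly.  tau2 sets
        the speed of neuronal integration (reaction times scale with
        1/tau2).
    d1, d2 : float
        Connection densities within a decision pool (d1) and everywhere
        else (d2).
    input_fraction : float
        Fraction of each pool receiving the external Poisson drive.
    seed : int or None
        Seed for structure generation when no explicit RNG is supplied.
    strict_theta_domain : bool
        If True, restrict theta0 to (0.1, 0.2), the range in which the
        inhibition both lets a full pool be active and forbids both
        pools being active at once.  Alpha-oscillation runs modulate
        Theta outside this band transiently, which is why the domain
        check applies to the baseline constant only.
    update_at_expiry : bool
        If True (default), a neuron is re-evaluated exactly when its
        refractory period expires, in addition to the random update
        events.  This is what lets sustained decision-state firing
        approach the 70-Hz single-neuron cap; switching it off leaves
        only the random schedule (mean wait 1/tau2 after expiry) and
        depresses attainable single-neuron rates far below the cap.
    """

    N: int = 1000
    n: int = 100
    theta0: float = 0.13
    tau1: float = 0.07
    tau2: float = 0.006
    d1: float = 0.55
    d2: float = 0.36
    input_fraction: float = 0.5
    seed: int | None = None
    strict_theta_domain: bool = True
    update_at_expiry: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.n <= self.N // 2):
            raise ValueError(f"pool size must satisfy 0 < n <= N/2, got n={self.n}, N={self.N}")
        if not (0 <= self.d2 <= self.d1 <= 1):
            raise ValueError(f"densities must satisfy 0 <= d2 <= d1 <= 1, got d1={self.d1}, d2={self.d2}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1 and tau2 must be positive")
        if not (0 < self.theta0 <= 1):
            raise ValueError(f"theta0 must lie in (0, 1], got {self.theta0}")
        if self.strict_theta_domain and not (0.1 <= self.theta0 <= 0.2):
            raise ValueError(
                f"theta0={self.theta0} outside the admissible domain [0.1, 0.2]: "
                "values below 0.1 keep a full decision pool from being active at once; "
                "values above 0.2 can violate winner-take-all"
            )
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must lie in (0, 1]")

    @property
    def refractory_ms(self) -> float:
        """Refractory duration 1/tau1 in ms."""
        return 1.0 / self.tau1

    def with_(self, **kwargs) -> "NetworkConfig":
        return replace(self, **kwargs)


@dataclass
class ConnectionMatrix:
    """Binary directed synaptic weights plus pool/input-target bookkeeping.

    ``weights[i, j] == 1`` means neuron ``i`` projects to neuron ``j``.
    The matrix carries no symmetry constraint.
    """

    weights: np.ndarray
    pool_A: np.ndarray
    pool_B: np.ndarray
    input_targets_A: np.ndarray
    input_targets_B: np.ndarray

    # caches for the event engine
    _csr: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def N(self) -> int:
        return self.weights.shape[0]

    def in_degrees(self) -> np.ndarray:
        """Number of presynaptic connections per neuron (column sums)."""
        return np.asarray(self.weights.sum(axis=0), dtype=np.int64).ravel()

    def out_neighbors_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR layout of outgoing edges: (indptr, indices).

        Row ``i`` of the CSR lists the postsynaptic targets of neuron
        ``i``; used by the event engine to update presynaptic-activity
        counters incrementally on each spike and refractory expiry.
        """
        if self._csr is None:
            src, dst = np.nonzero(self.weights)
            counts = np.bincount(src, minlength=self.N)
            indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
            self._csr = (indptr, dst.astype(np.int32))
        return self._csr

    def to_edge_list(self, path) -> None:
        """Serialize as a sparse edge list: one ``i j`` pair per line
        (0-based), preceded by a JSON header line with pool index ranges."""
        header = {
            "N": int(self.N),
            "pool_A": [int(self.pool_A[0]), int(self.pool_A[-1])],
            "pool_B": [int(self.pool_B[0]), int(self.pool_B[-1])],
            "input_targets_A": [int(i) for i in self.input_targets_A],
            "input_targets_B": [int(i) for i in self.input_targets_B],
        }
        src, dst = np.nonzero(self.weights)
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            for i, j in zip(src, dst):
                fh.write(f"{i} {j}\n")

    @classmethod
    def from_edge_list(cls, path) -> "ConnectionMatrix":
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            N = header["N"]
            weights = np.zeros((N, N), dtype=np.uint8)
            for line in fh:
                i, j = line.split()
                weights[int(i), int(j)] = 1
        a0, a1 = header["pool_A"]
        b0, b1 = header["pool_B"]
        return cls(
            weights=weights,
            pool_A=np.arange(a0, a1 + 1),
            pool_B=np.arange(b0, b1 + 1),
            input_targets_A=np.asarray(header["input_targets_A"], dtype=np.int64),
            input_targets_B=np.asarray(header["input_targets_B"], dtype=np.int64),
        )


@dataclass
class NetworkState:
    """Instantaneous state of the network.

    ``s[j] == 1`` iff neuron ``j`` is refractory at time ``t``, i.e.
    ``t - last_spike_time[j] < 1/tau1``.  ``last_spike_time`` is -inf
    for neurons that have never spiked.
    """

    s: np.ndarray
    last_spike_time: np.ndarray
    t: float = 0.0

    def active_count(self) -> int:
        return int(self.s.sum())


def generate_connectivity(config: NetworkConfig, rng: np.random.Generator | None = None) -> ConnectionMatrix:
    """Draw a fresh random connection matrix.

    Each ordered pair (i, j), i != j, receives a connection independently
    with probability ``d1`` when i and j belong to the same decision pool
    and ``d2`` otherwise.  Self-connections are excluded.  Input-target
    subsets (the pool neurons receiving external drive) are drawn without
    replacement.  Connectivity is regenerated before each simulated trial
    unless explicitly frozen.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, n = config.N, config.n
    u = rng.random((N, N))
    weights = (u < config.d2).astype(np.uint8)
    pool_A = np.arange(0, n)
    pool_B = np.arange(n, 2 * n)
    # within-pool blocks re-thresholded on the same uniforms at density d1
    weights[:n, :n] = u[:n, :n] < config.d1
    weights[n : 2 * n, n : 2 * n] = u[n : 2 * n, n : 2 * n] < config.d1
    np.fill_diagonal(weights, 0)
    k = int(round(n * config.input_fraction))
    targets_A = np.sort(rng.choice(pool_A, size=k, replace=False))
    targets_B = np.sort(rng.choice(pool_B, size=k, replace=False))
    return ConnectionMatrix(weights, pool_A, pool_B, targets_A, targets_B)


def initialize_state(config: NetworkConfig, rng: np.random.Generator | None = None) -> NetworkState:
    """Random non-zero initial state: each neuron refractory with probability Theta.

    Initially active neurons are assigned a refractory phase drawn
    uniformly over the refractory period (last spike time in (-1/tau1, 0],
    not recorded as a spike), so their refractory windows expire spread
    over (0, 1/tau1].  A common entry time would make the whole initial
    cohort expire at one instant and, because co-expiring neurons are
    mutually invisible to the update rule at that instant, refire as a
    permanently phase-locked assembly — an artifact of initialization,
    not a property of the model, which otherwise never produces two
    spikes at the same instant.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s = (rng.random(config.N) < config.theta0).astype(np.uint8)
    phase = rng.random(config.N) * config.refractory_ms
    last = np.where(s == 1, -phase, -np.inf)
    return NetworkState(s=s, last_spike_time=last, t=0.0)


def evaluate_update(
    state: NetworkState,
    conn: ConnectionMatrix,
    j: int,
    theta_t: float,
    external_count: float = 0.0,
) -> int:
    """Apply the global-inhibition update rule to neuron ``j``.

    Returns 1 (spike) iff

        (sum_i s(i) w_ij + external_count) / (sum_i w_ij)
            > (1 / theta_t) * (sum_i s(i) / N)**2

    with strict inequality; 0 otherwise.  ``external_count`` is the
    stimulus drive delivered to input-target neurons during a stimulus
    window; it adds presynaptic spikes to the numerator only, since the
    rule normalizes by the recurrent in-degree.  A neuron with zero
    in-degree never fires (the 0/0 case is defined as 0).
    """
    if state.s[j]:
        raise ValueError(f"neuron {j} is refractory at t={state.t}; refractory neurons are not evaluated")
    in_deg = int(conn.weights[:, j].sum())
    if in_deg == 0:
        return 0
    lhs = (float(state.s @ conn.weights[:, j]) + external_count) / in_deg
    rhs = (state.s.sum() / conn.N) ** 2 / theta_t
    return 1 if lhs > rhs else 0
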
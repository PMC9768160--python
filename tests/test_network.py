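"""Structure generation and the single-neuron update rule."""

import numpy as np
import pytest

from satnet import (
    NetworkConfig,
    ConnectionMatrix,
    NetworkState,
    evaluate_update,
    generate_connectivity,
    initialize_state,
)


def _binomial_band(p, n, k=3.0):
    se = np.sqrt(p * (1 - p) / n)
    return p - k * se, p + k * se


class TestConnectivity:
    def test_block_densities_match_their_targets(self, default_config, rng):
        conn = generate_connectivity(default_config, rng)
        W = conn.weights
        n = default_config.n
        pool_block = W[:n, :n]
        n_pairs = n * (n - 1)
        d_pool = (pool_block.sum() - np.trace(pool_block)) / n_pairs
        lo, hi = _binomial_band(default_config.d1, n_pairs)
        assert lo < d_pool < hi
        bg = W[2 * n :, 2 * n :]
        m = bg.shape[0]
        d_bg = (bg.sum() - np.trace(bg)) / (m * (m - 1))
        lo, hi = _binomial_band(default_config.d2, m * (m - 1))
        assert lo < d_bg < hi

    def test_no_self_connections_and_binary_weights(self, default_config, rng):
        conn = generate_connectivity(default_config, rng)
        assert np.trace(conn.weights) == 0
        assert set(np.unique(conn.weights)) <= {0, 1}

    def test_zero_densities_give_empty_graph(self, rng):
        cfg = NetworkConfig(d1=0.0, d2=0.0)
        conn = generate_connectivity(cfg, rng)
        assert conn.weights.sum() == 0

    def test_directed_asymmetry_fraction(self, default_config, rng):
        # among background pairs, P(w_ij != w_ji) = 2 d2 (1 - d2)
        conn = generate_connectivity(default_config, rng)
        n = default_config.n
        bg = conn.weights[2 * n :, 2 * n :]
        iu = np.triu_indices(bg.shape[0], k=1)
        mismatch = (bg[iu] != bg.T[iu]).mean()
        p = 2 * default_config.d2 * (1 - default_config.d2)
        lo, hi = _binomial_band(p, len(iu[0]))
        assert lo < mismatch < hi

    def test_input_targets_are_pool_subsets_without_replacement(self, default_config, rng):
        conn = generate_connectivity(default_config, rng)
        k = int(default_config.n * default_config.input_fraction)
        assert len(set(conn.input_targets_A)) == k
        assert set(conn.input_targets_A) <= set(conn.pool_A)
        assert set(conn.input_targets_B) <= set(conn.pool_B)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError, match="densities"):
            NetworkConfig(d1=0.3, d2=0.5)  # d2 > d1

    def test_edge_list_round_trip(self, rng, tmp_path):
        cfg = NetworkConfig(N=40, n=10, tau2=0.05)
        conn = generate_connectivity(cfg, rng)
        path = tmp_path / "edges.txt"
        conn.to_edge_list(path)
        back = ConnectionMatrix.from_edge_list(path)
        assert np.array_equal(back.weights, conn.weights)
        assert np.array_equal(back.input_targets_A, conn.input_targets_A)


class TestInitializeState:
    def test_active_fraction_matches_theta(self, default_config):
        rng = np.random.default_rng(7)
        counts = [initialize_state(default_config, rng).active_count() for _ in range(100)]
        frac = np.mean(counts) / default_config.N
        lo, hi = _binomial_band(default_config.theta0, 100 * default_config.N)
        assert lo < frac < hi

    def test_degenerate_probability_one_activates_everyone(self, rng):
        cfg = NetworkConfig(theta0=1.0, strict_theta_domain=False)
        state = initialize_state(cfg, rng)
        assert state.active_count() == cfg.N
        # refractory phases staggered over (-1/tau1, 0]
        assert (state.last_spike_time <= 0.0).all()
        assert (state.last_spike_time > -cfg.refractory_ms).all()

    def test_inactive_neurons_have_no_spike_history(self, default_config, rng):
        state = initialize_state(default_config, rng)
        assert np.isneginf(state.last_spike_time[state.s == 0]).all()
        assert state.t == 0.0


def _hand_network(N, edges_in, j, n_active_presyn, n_active_total):
    """Build an explicit network where neuron j has `edges_in` presynaptic
    connections of which the first `n_active_presyn` sources are active;
    total active network-wide is n_active_total."""
    W = np.zeros((N, N), dtype=np.uint8)
    for i in range(edges_in):
        W[i + 1, j] = 1
    conn = ConnectionMatrix(W, np.arange(2), np.arange(2, 4), np.arange(1), np.arange(2, 3))
    s = np.zeros(N, dtype=np.uint8)
    s[1 : 1 + n_active_presyn] = 1
    extra = n_active_total - n_active_presyn
    s[N - extra : N] = 1
    assert s.sum() == n_active_total and s[j] == 0
    last = np.where(s == 1, 0.0, -np.inf)
    return conn, NetworkState(s=s, last_spike_time=last, t=0.0)


class TestEvaluateUpdate:
    def test_silent_network_cannot_ignite(self):
        conn, state = _hand_network(N=10, edges_in=4, j=0, n_active_presyn=0, n_active_total=0)
        assert evaluate_update(state, conn, 0, theta_t=0.13, external_count=0.0) == 0

    def test_hand_worked_threshold_comparison(self):
        # LHS = 2/4 = 0.5; RHS = (3/10)^2 / 0.13 ~ 0.692 -> no spike
        conn, state = _hand_network(N=10, edges_in=4, j=0, n_active_presyn=2, n_active_total=3)
        assert evaluate_update(state, conn, 0, theta_t=0.13) == 0
        # same inputs but theta large enough to drop RHS below 0.5 -> spike
        assert evaluate_update(state, conn, 0, theta_t=0.5) == 1

    def test_saturation_is_self_limiting(self):
        # all other neurons active: RHS >= (0.9)^2/theta > 1 >= LHS
        conn, state = _hand_network(N=10, edges_in=4, j=0, n_active_presyn=4, n_active_total=9)
        assert evaluate_update(state, conn, 0, theta_t=0.13) == 0

    def test_zero_in_degree_defined_as_silent(self):
        conn, state = _hand_network(N=10, edges_in=0, j=0, n_active_presyn=0, n_active_total=3)
        assert evaluate_update(state, conn, 0, theta_t=0.13, external_count=5.0) == 0

    def test_refractory_neuron_rejected(self):
        conn, state = _hand_network(N=10, edges_in=4, j=0, n_active_presyn=2, n_active_total=3)
        state.s[0] = 1
        with pytest.raises(ValueError, match="refractory"):
            evaluate_update(state, conn, 0, theta_t=0.13)

    @pytest.mark.parametrize("theta", [0.05, 0.13, 0.3, 0.8])
    @pytest.mark.parametrize("k_active", [1, 2, 3])
    def test_decision_invariant_under_presynaptic_duplication(self, theta, k_active):
        # scaling numerator and denominator of the LHS by a common factor
        # (duplicating every presynaptic source with its state, holding
        # global activity fixed) leaves the firing decision unchanged
        total = 8
        base, state = _hand_network(N=20, edges_in=4, j=0, n_active_presyn=k_active, n_active_total=total)
        doubled, state2 = _hand_network(N=20, edges_in=8, j=0, n_active_presyn=2 * k_active, n_active_total=total)
        r1 = evaluate_update(state, base, 0, theta_t=theta)
        r2 = evaluate_update(state2, doubled, 0, theta_t=theta)
        assert r1 == r2


class TestConfigValidation:
    def test_pool_size_bound(self):
        with pytest.raises(ValueError, match="n <= N/2"):
            NetworkConfig(N=100, n=60)

    def test_theta_domain_enforced_by_default(self):
        with pytest.raises(ValueError, match="winner-take-all"):
            NetworkConfig(theta0=0.25)
        # explicit opt-out for exploratory work
        NetworkConfig(theta0=0.25, strict_theta_domain=False)

    def test_refractory_duration(self, default_config):
        assert default_config.refractory_ms == pytest.approx(14.2857, abs=1e-3)
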
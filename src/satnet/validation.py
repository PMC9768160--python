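"""Reproduction of the study's headline quantities at configurable scale.

Each routine regenerates its inputs, runs the simulation experiments and
measures one group of published statistics: attractor-state firing
rates, the gain-modulation regressions, the alpha-oscillation effects,
and the dot-motion psychometric pipeline.  The acceptance script and the
acceptance test suite both call these functions; trial counts default to
desk scale (a tenth or less of the study's sizes), which widens the
Monte-Carlo error bands but leaves every condition definition unchanged.
"""

from __future__ import annotations

import numpy as np

from . import experiments, stats
from .engine import StimulusDrive, TrialProtocol, run_trial
from .metrics import decision_occupancy_mask, sustained_above
from .network import NetworkConfig

__all__ = [
    "derive_seed",
    "spontaneous_state_rate",
    "decision_state_rates",
    "gain_regressions",
    "alpha_condition",
    "alpha_baseline_regression",
    "dot_motion_summary",
]


def derive_seed(master_seed: int, stream: int) -> int:
    """Independent sub-seed for one measurement stream."""
    return int(np.random.SeedSequence([int(master_seed), int(stream)]).generate_state(1)[0] % (2**31))


def spontaneous_state_rate(
    n_runs: int = 20,
    run_ms: float = 5000.0,
    seed: int = 0,
    settle_ms: float = 500.0,
) -> dict:
    """Mean decision-pool rate during the spontaneous state.

    Runs the network without any external input and averages both pools'
    30-ms-window rates across windows and runs, after a settling period.
    Windows after a committed escape to a decision state (a sustained
    crossing of the 50-Hz attractor floor) are excluded: the statistic
    describes the spontaneous state, and escapes out of it are a
    separate, much slower process.
    """
    cfg = NetworkConfig()
    proto = TrialProtocol(pre_ms=0.0, max_decision_ms=run_ms, decision_threshold_hz=1e9)
    vals, sds = [], []
    for i in range(n_runs):
        r = run_trial(cfg, None, None, proto, rng=derive_seed(seed, 100 + i),
                      detect=False, keep_spikes=False)
        sel = r.times >= settle_ms
        ra, rb = r.rates_A[sel], r.rates_B[sel]
        cut = len(ra)
        for arr in (ra, rb):
            esc = sustained_above(arr, 50.0)
            if esc is not None:
                cut = min(cut, esc)
        if cut == 0:
            continue
        vals.append((ra[:cut].mean() + rb[:cut].mean()) / 2.0)
        sds.append(np.concatenate([ra[:cut], rb[:cut]]).std())
    return {"mean_rate_hz": float(np.mean(vals)), "window_sd_hz": float(np.mean(sds)), "n": len(vals)}


def decision_state_rates(n_trials: int = 24, seed: int = 0) -> dict:
    """Winning- and losing-pool rates while the network occupies a decision state.

    Trials are driven to a decision with strong coherent evidence
    (c = 51.2%, threshold 50 Hz); the stimulus is withdrawn after 800 ms
    and both pools are measured over the following settle window, on the
    grid samples where the network occupies the decision attractor
    (winner >= 50 Hz, loser <= 20 Hz, sustained 100 ms).
    """
    cfg = NetworkConfig()
    drive = StimulusDrive(mode="coherence", c=0.512, duration_ms=800.0)
    proto = TrialProtocol(pre_ms=1000.0, max_decision_ms=800.0, decision_threshold_hz=50.0)
    wins, loses = [], []
    for i in range(n_trials):
        r = run_trial(cfg, drive, None, proto, rng=derive_seed(seed, 200 + i),
                      post_decision_ms=2300.0, keep_spikes=False)
        if r.choice == "none":
            continue
        sel = (r.times > r.onset_ms + 900.0) & (r.times <= r.onset_ms + 2300.0)
        w = (r.rates_A if r.choice == "A" else r.rates_B)[sel]
        l = (r.rates_B if r.choice == "A" else r.rates_A)[sel]
        mask = decision_occupancy_mask(w, l)
        if mask.any():
            wins.append(w[mask].mean())
            loses.append(l[mask].mean())
    return {
        "winner_rate_hz": float(np.mean(wins)),
        "loser_rate_hz": float(np.mean(loses)),
        "n": len(wins),
    }


def gain_regressions(n_trials: int = 500, seed: int = 0, n_boot: int = 10_000) -> dict:
    """Baseline-rate and integration-speed regressions on the inhibition constant.

    Trials draw Theta ~ U(0.1, 0.2) and contrast ~ U(4.98, 13.53)% with a
    fixed 50-Hz threshold; the baseline rate of the 1000-ms pre-stimulus
    epoch and the integration speed of decided trials are regressed on
    Theta with percentile-bootstrap confidence intervals.
    """
    spec = experiments.ExperimentSpec("gain_sweep", trials_per_cell=n_trials, master_seed=derive_seed(seed, 3))
    table = experiments.run_gain_sweep(spec, design="regression")
    base = stats.ols_slope_boot(table["theta0"], table["baseline_rate_hz"],
                                n_boot=n_boot, rng=derive_seed(seed, 31))
    dec = table[table["decided"] & table["integration_speed"].notna()]
    speed = stats.ols_slope_boot(dec["theta0"], dec["integration_speed"],
                                 n_boot=n_boot, rng=derive_seed(seed, 32))
    return {"baseline": base, "integration_speed": speed, "table": table}


def alpha_condition(
    amplitude_range: tuple[float, float],
    n_trials: int = 300,
    seed: int = 0,
    contrast_pct: float = 8.21,
) -> dict:
    """Accuracy and no-decision statistics for one alpha-amplitude condition.

    Decisions are scored over 2500 ms at a 50-Hz threshold; percent
    correct keeps all runs (no-decisions included) in the denominator.
    ``amplitude_range=(0, 0)`` is the no-alpha baseline.
    """
    spec = experiments.ExperimentSpec(
        "alpha_study", trials_per_cell=n_trials, master_seed=derive_seed(seed, 4),
        grids={"amplitude_range": tuple(amplitude_range), "contrasts_pct": (contrast_pct,)},
    )
    table = experiments.run_alpha_experiment(spec)
    n = len(table)
    return {
        "pct_correct_all_runs": 100.0 * float((table["choice"] == "A").mean()),
        "pct_no_decision": 100.0 * float((table["choice"] == "none").mean()),
        "n": n,
        "table": table,
    }


def alpha_baseline_regression(n_trials: int = 300, seed: int = 0, n_boot: int = 10_000) -> dict:
    """Baseline-rate-vs-amplitude regression from alpha-modulated pre-epochs.

    Amplitude is uniform on (0, 0.1) with random frequency and phase;
    the baseline rate of each trial's 1000-ms pre-stimulus epoch (alpha
    applied throughout) is regressed on amplitude.
    """
    spec = experiments.ExperimentSpec(
        "alpha_study", trials_per_cell=n_trials, master_seed=derive_seed(seed, 5),
        grids={"amplitude_range": (0.0, 0.1)},
    )
    table = experiments.run_alpha_experiment(spec, design="regression")
    res = stats.ols_slope_boot(table["alpha_amp"], table["baseline_rate_hz"],
                               n_boot=n_boot, rng=derive_seed(seed, 51))
    return {"baseline": res, "table": table}


def dot_motion_summary(trials_per_level: int = 300, seed: int = 0) -> dict:
    """Psychometric fit and exclusion fraction of the dot-motion pipeline.

    Coherence levels {0, 3.2, 6.4, 12.8, 25.6, 51.2}%, threshold
    52.5 Hz, 2-s stimulus, standard exclusions (no-decision, RT > 2000,
    RT < 100 ms); percent correct per surviving level is fitted with the
    Weibull psychometric function.
    """
    spec = experiments.ExperimentSpec(
        "dot_motion", trials_per_cell=trials_per_level, master_seed=derive_seed(seed, 6)
    )
    table = experiments.run_dot_motion(spec)
    table = experiments.apply_exclusions(table, experiments.DOT_MOTION_RULES)
    kept = table[~table["excluded"]]
    cs, pcs = [], []
    for c_pct, grp in kept.groupby("coherence_pct"):
        cs.append(float(c_pct))
        if c_pct == 0:
            pcs.append(float((grp["choice"] == "A").mean()))
        else:
            pcs.append(float(grp["correct"].mean()))
    fit = stats.fit_weibull(np.array(cs), np.array(pcs))
    return {
        "weibull_alpha": fit.alpha,
        "weibull_beta": fit.beta,
        "pct_excluded": 100.0 * float(table["excluded"].mean()),
        "pct_correct_by_level": dict(zip(cs, pcs)),
        "n": len(table),
        "table": table,
    }
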
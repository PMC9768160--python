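"""The five simulation studies, as reproducible drivers producing trial tables.

Each driver runs independent trials of the decision network under a
declared condition grid and returns a tidy :class:`pandas.DataFrame`
(one row per trial, or per trial x threshold where several readout
thresholds are evaluated on the same simulated activity).  Stronger
evidence always goes to pool A, so a trial is correct when pool A wins;
at zero stimulus strength correctness is undefined.

Per-trial seeds are derived from (master_seed, cell id, trial index), so
any row can be re-simulated in isolation regardless of execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .engine import AlphaModulation, StimulusDrive, TrialProtocol, run_trial
from .network import NetworkConfig

__all__ = [
    "ExperimentSpec",
    "trial_seed",
    "apply_exclusions",
    "summarize_cells",
    "run_dot_motion",
    "run_threshold_sweep",
    "run_input_space_mc",
    "run_gain_sweep",
    "run_alpha_experiment",
    "DOT_MOTION_RULES",
    "RT_DIFF_RULES",
    "COHERENCE_LEVELS_PCT",
    "CONTRAST_LEVELS_PCT",
    "THRESHOLD_GRID_HZ",
]

# the published condition grids
COHERENCE_LEVELS_PCT = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)
CONTRAST_LEVELS_PCT = (4.98, 6.39, 8.21, 10.54, 13.53)
THRESHOLD_GRID_HZ = (20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)

# exclusion-rule sets: dot-motion removes no-decisions, slow (> 2000 ms)
# and anticipatory (< 100 ms) decisions; RT-difference analyses keep the
# fast ones.
DOT_MOTION_RULES = ("no_decision", "rt_above_2000", "rt_below_100")
RT_DIFF_RULES = ("no_decision", "rt_above_2000")

_RULE_PREDICATES = {
    "no_decision": lambda df: ~df["decided"].astype(bool),
    "rt_above_2000": lambda df: df["decided"].astype(bool) & (df["rt_ms"] > 2000),
    "rt_below_100": lambda df: df["decided"].astype(bool) & (df["rt_ms"] < 100),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """Sweep definition for one experiment.

    ``scale`` multiplies all per-cell trial counts (desk-scale runs use
    values well below 1); condition definitions never change with scale.
    """

    experiment: str
    trials_per_cell: int
    master_seed: int = 0
    scale: float = 1.0
    grids: dict = field(default_factory=dict)

    def n_trials(self) -> int:
        n = max(1, int(round(self.trials_per_cell * self.scale)))
        return n


def trial_seed(master_seed: int, cell_id: str, trial_index: int) -> int:
    """Stable per-trial seed: hash of (master seed, cell id, trial index)."""
    cell_hash = zlib.crc32(cell_id.encode())
    ss = np.random.SeedSequence([int(master_seed), int(cell_hash), int(trial_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def apply_exclusions(table: pd.DataFrame, rules=DOT_MOTION_RULES) -> pd.DataFrame:
    """Flag (never delete) rows violating the active rule set.

    Adds boolean ``excluded`` and string ``exclusion_reason`` columns;
    each excluded row carries exactly one reason (the first matching
    rule in the given order).
    """
    for rule in rules:
        if rule not in _RULE_PREDICATES:
            raise ValueError(f"unknown exclusion rule {rule!r}")
    out = table.copy()
    excluded = np.zeros(len(out), dtype=bool)
    reason = np.array([""] * len(out), dtype=object)
    if out.empty:
        out["excluded"] = excluded
        out["exclusion_reason"] = reason
        return out
    for rule in rules:
        hit = _RULE_PREDICATES[rule](out).to_numpy() & ~excluded
        excluded |= hit
        reason[hit] = rule
    out["excluded"] = excluded
    out["exclusion_reason"] = reason
    return out


def _finalize(rows: list[dict]) -> pd.DataFrame:
    """Build the trial table; "correct" becomes float (1/0/NaN) so that
    aggregation never falls into pandas object-dtype arithmetic."""
    df = pd.DataFrame(rows)
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype(float)
    return df


def _row_base(cell_id: str, idx: int, seed: int, trial) -> dict:
    row = {
        "cell_id": cell_id,
        "trial_index": idx,
        "trial_seed": seed,
        "choice": trial.choice,
        "decided": trial.decided,
        "rt_ms": trial.rt_ms if trial.decided else np.nan,
    }
    return row


def _trial_metrics(trial) -> dict:
    series = metrics.RateSeries.from_trial(trial)
    out = {"baseline_rate_hz": metrics.baseline_rate(trial)}
    if trial.decided:
        out["integration_speed"] = metrics.integration_speed(
            series, trial.onset_ms, trial.onset_ms + trial.rt_ms, trial.choice
        )
    else:
        out["integration_speed"] = np.nan
    return out


def run_dot_motion(spec: ExperimentSpec, progress=None) -> pd.DataFrame:
    """Dot-motion discrimination validation run.

    Coherence-mode Poisson inputs at the six published coherence levels,
    decision threshold 52.5 Hz, 2-s stimulus after 1 s of spontaneous
    run.  Feeds the Weibull psychometric fit and the RT analyses.
    """
    coherences = spec.grids.get("coherences_pct", COHERENCE_LEVELS_PCT)
    threshold = spec.grids.get("threshold_hz", 52.5)
    n = spec.n_trials()
    proto = TrialProtocol(pre_ms=1000.0, max_decision_ms=2000.0, decision_threshold_hz=threshold)
    rows = []
    for c_pct in coherences:
        cell = f"dot_motion/c={c_pct}"
        drive = StimulusDrive(mode="coherence", c=c_pct / 100.0, duration_ms=2000.0)
        for i in range(n):
            seed = trial_seed(spec.master_seed, cell, i)
            trial = run_trial(NetworkConfig(), drive, None, proto, rng=seed, keep_spikes=False)
            row = _row_base(cell, i, seed, trial)
            row.update(coherence_pct=c_pct, threshold_hz=threshold,
                       correct=(trial.choice == "A") if (c_pct > 0 and trial.decided) else np.nan)
            rows.append(row)
            if progress:
                progress()
    return _finalize(rows)


def _posthoc_rows(trial, thresholds, onset, deadline, cell, i, seed, rng) -> list[dict]:
    """Evaluate several readout thresholds on one simulated trial."""
    series = metrics.RateSeries.from_trial(trial)
    rows = []
    for thr in thresholds:
        choice, rt = metrics.detect_decision(series, thr, onset, deadline, rng=rng)
        decided = choice != "none"
        row = {
            "cell_id": cell, "trial_index": i, "trial_seed": seed,
            "threshold_hz": thr, "choice": choice, "decided": decided,
            "rt_ms": rt if decided else np.nan,
            "baseline_rate_hz": metrics.baseline_rate(trial),
        }
        if decided:
            row["integration_speed"] = metrics.integration_speed(series, onset, onset + rt, choice)
        else:
            row["integration_speed"] = np.nan
        rows.append(row)
    return rows


def run_threshold_sweep(spec: ExperimentSpec, progress=None) -> pd.DataFrame:
    """SAT through decision-threshold manipulation.

    Contrast-mode stimuli at the five published contrast levels; each
    simulated trial is read out at every threshold of the 20-50 Hz grid
    (the decision variable is identical across thresholds, so readouts
    share the underlying activity, which also pairs the RT-vs-threshold
    comparison trial by trial).
    """
    contrasts = spec.grids.get("contrasts_pct", CONTRAST_LEVELS_PCT)
    thresholds = spec.grids.get("thresholds_hz", THRESHOLD_GRID_HZ)
    n = spec.n_trials()
    proto = TrialProtocol(pre_ms=1000.0, max_decision_ms=2000.0, decision_threshold_hz=max(thresholds))
    rows = []
    for c_pct in contrasts:
        cell = f"threshold_sweep/c={c_pct}"
        drive = StimulusDrive(mode="contrast", c=c_pct / 100.0)
        for i in range(n):
            seed = trial_seed(spec.master_seed, cell, i)
            rng = np.random.default_rng(seed)
            trial = run_trial(NetworkConfig(), drive, None, proto, rng=rng, detect=False, keep_spikes=False)
            for row in _posthoc_rows(trial, thresholds, proto.pre_ms, proto.pre_ms + proto.max_decision_ms,
                                     cell, i, seed, rng):
                row["contrast_pct"] = c_pct
                row["correct"] = (row["choice"] == "A") if row["decided"] else np.nan
                rows.append(row)
            if progress:
                progress()
    return _finalize(rows)


def run_input_space_mc(spec: ExperimentSpec, progress=None) -> pd.DataFrame:
    """Monte-Carlo exploration of the raw input space.

    lambda_A, lambda_B are drawn uniformly from (0, 20)^2 per trial
    (threshold 50 Hz).  The resulting table feeds the accuracy-vs-input-
    sum curve and the neighborhood RT-sign map; "correct" means choosing
    the pool with the larger input.
    """
    n = spec.n_trials()
    lam_range = spec.grids.get("lambda_range", (0.0, 20.0))
    proto = TrialProtocol(pre_ms=1000.0, max_decision_ms=2000.0, decision_threshold_hz=50.0)
    cell = "input_space_mc"
    rows = []
    for i in range(n):
        seed = trial_seed(spec.master_seed, cell, i)
        rng = np.random.default_rng(seed)
        la, lb = rng.uniform(lam_range[0], lam_range[1], size=2)
        drive = StimulusDrive(mode="raw", lambda_A=float(la), lambda_B=float(lb))
        trial = run_trial(NetworkConfig(), drive, None, proto, rng=rng, keep_spikes=False)
        row = _row_base(cell, i, seed, trial)
        correct = np.nan
        if trial.decided and la != lb:
            correct = (trial.choice == "A") == (la > lb)
        row.update(lambda_A=la, lambda_B=lb, input_sum=la + lb, correct=correct)
        rows.append(row)
        if progress:
            progress()
    return _finalize(rows)


def run_gain_sweep(spec: ExperimentSpec, design: str = "sat", progress=None) -> pd.DataFrame:
    """SAT through excitability (inhibition-constant) manipulation.

    ``design="sat"``: the five contrast levels with Theta drawn
    uniformly from (0.1, 0.2) per trial and a fixed 50-Hz threshold.
    ``design="regression"``: contrast drawn uniformly from
    (4.98, 13.53)% per trial, recording the baseline rate of the
    pre-stimulus epoch and the integration speed of decided trials for
    the baseline/integration-speed regressions on Theta.
    """
    if design not in ("sat", "regression"):
        raise ValueError(f"unknown design {design!r}")
    theta_range = spec.grids.get("theta_range", (0.1, 0.2))
    proto = TrialProtocol(pre_ms=1000.0, max_decision_ms=2000.0, decision_threshold_hz=50.0)
    n = spec.n_trials()
    rows = []
    if design == "sat":
        contrasts = spec.grids.get("contrasts_pct", CONTRAST_LEVELS_PCT)
        cells = [(f"gain_sweep/c={c}", c) for c in contrasts]
    else:
        cells = [("gain_sweep/regression", None)]
    for cell, c_fixed in cells:
        for i in range(n):
            seed = trial_seed(spec.master_seed, cell, i)
            rng = np.random.default_rng(seed)
            theta = float(rng.uniform(*theta_range))
            c_pct = c_fixed if c_fixed is not None else float(rng.uniform(4.98, 13.53))
            drive = StimulusDrive(mode="contrast", c=c_pct / 100.0)
            cfg = NetworkConfig(theta0=theta)
            trial = run_trial(cfg, drive, None, proto, rng=rng, keep_spikes=False)
            row = _row_base(cell, i, seed, trial)
            row.update(theta0=theta, contrast_pct=c_pct, threshold_hz=50.0,
                       correct=(trial.choice == "A") if trial.decided else np.nan)
            row.update(_trial_metrics(trial))
            rows.append(row)
            if progress:
                progress()
    return _finalize(rows)


def run_alpha_experiment(
    spec: ExperimentSpec,
    design: str = "discrimination",
    progress=None,
) -> pd.DataFrame:
    """Interference of alpha oscillations with the decision process.

    ``design="discrimination"``: the five contrast levels with random
    amplitude (0-0.1), frequency (8-12 Hz) and phase per trial;
    decisions scored over 2500 ms at a 50-Hz threshold.  A fixed
    amplitude range can be imposed through ``grids["amplitude_range"]``
    (e.g. the optimal band (0.05, 0.06)); ``(0, 0)`` disables the
    oscillation for the no-alpha baseline.
    ``design="rt"``: same drive but every trial is read out on the
    35-50-Hz threshold grid for the RT-vs-amplitude analysis.
    ``design="regression"``: contrast uniform in (4.98, 13.53)%,
    recording baseline rate (pre-epoch, alpha on throughout) and
    integration speed for the amplitude regressions.
    """
    if design not in ("discrimination", "rt", "regression"):
        raise ValueError(f"unknown design {design!r}")
    amp_range = spec.grids.get("amplitude_range", (0.0, 0.1))
    freq_range = spec.grids.get("frequency_range", (8.0, 12.0))
    deadline = spec.grids.get("max_decision_ms", 2500.0)
    thresholds = spec.grids.get("thresholds_hz", (35.0, 40.0, 45.0, 50.0)) if design == "rt" else (50.0,)
    n = spec.n_trials()
    proto = TrialProtocol(pre_ms=1000.0, max_decision_ms=deadline, decision_threshold_hz=max(thresholds))
    if design == "regression":
        cells = [("alpha/regression", None)]
    else:
        contrasts = spec.grids.get("contrasts_pct", CONTRAST_LEVELS_PCT)
        cells = [(f"alpha/c={c}", c) for c in contrasts]
    rows = []
    for cell, c_fixed in cells:
        for i in range(n):
            seed = trial_seed(spec.master_seed, cell, i)
            rng = np.random.default_rng(seed)
            amp = float(rng.uniform(*amp_range))
            freq = float(rng.uniform(*freq_range))
            phase = float(rng.uniform(0.0, 2.0 * np.pi))
            mod = AlphaModulation(amplitude=amp, frequency_hz=freq, phase=phase) if amp > 0 else None
            c_pct = c_fixed if c_fixed is not None else float(rng.uniform(4.98, 13.53))
            drive = StimulusDrive(mode="contrast", c=c_pct / 100.0)
            cond = dict(alpha_amp=amp, alpha_freq_hz=freq, alpha_phase=phase,
                        contrast_pct=c_pct)
            if design == "rt":
                trial = run_trial(NetworkConfig(), drive, mod, proto, rng=rng, detect=False, keep_spikes=False)
                for row in _posthoc_rows(trial, thresholds, proto.pre_ms, proto.pre_ms + deadline,
                                         cell, i, seed, rng):
                    row.update(cond)
                    row["correct"] = (row["choice"] == "A") if row["decided"] else np.nan
                    rows.append(row)
            else:
                trial = run_trial(NetworkConfig(), drive, mod, proto, rng=rng, keep_spikes=False)
                row = _row_base(cell, i, seed, trial)
                row.update(cond, threshold_hz=50.0,
                           correct=(trial.choice == "A") if trial.decided else np.nan)
                row.update(_trial_metrics(trial))
                rows.append(row)
            if progress:
                progress()
    return _finalize(rows)


def summarize_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell summary of a trial table.

    Groups by ``cell_id`` (and ``threshold_hz`` when several readout
    thresholds share trials) and reports trial counts, accuracy, and the
    RT summaries: median and the error-correct mean difference on the
    deadline-censored subset (RT <= 2000 ms), SD/mean ratio and skewness
    on all decided trials.
    """
    from .stats import rt_summaries

    keys = ["cell_id"]
    if "threshold_hz" in table.columns and table["threshold_hz"].nunique() > 1:
        keys.append("threshold_hz")
    out = []
    for key, grp in table.groupby(keys):
        dec = grp[grp["decided"].astype(bool)]
        cens = dec[dec["rt_ms"] <= 2000]
        has_corr = "correct" in grp.columns
        corr_mask = cens["correct"] == True if has_corr else pd.Series(False, index=cens.index)  # noqa: E712
        summ = rt_summaries(
            cens.loc[corr_mask, "rt_ms"].to_numpy(float),
            cens.loc[cens["correct"] == False, "rt_ms"].to_numpy(float) if has_corr else np.array([]),  # noqa: E712
            dec["rt_ms"].to_numpy(float),
        )
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        n_corr_def = int(grp["correct"].notna().sum()) if has_corr else 0
        row.update(
            n_trials=len(grp),
            n_decided=len(dec),
            pct_correct=100.0 * grp["correct"].mean() if n_corr_def else np.nan,
            median_rt_ms=summ.median_rt,
            rt_diff_ec_ms=summ.rt_diff_ec if summ.rt_diff_ec is not None else np.nan,
            sd_mean_ratio=summ.sd_mean_ratio,
            skewness=summ.skewness,
        )
        out.append(row)
    return pd.DataFrame(out)
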
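"""Statistical procedures applied to trial tables.

Covers the discriminability index d', the Weibull psychometric fit, OLS
regression with t-statistics and percentile-bootstrap confidence
intervals, probit regression of accuracy on a covariate, RT-distribution
summaries, and the Monte-Carlo neighborhood map that classifies the sign
of the error-vs-correct RT difference over the two-dimensional input
space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
import statsmodels.api as sm

__all__ = [
    "WeibullFit",
    "RegressionResult",
    "RTSummary",
    "dprime",
    "fit_weibull",
    "weibull_pc",
    "ols_slope_boot",
    "probit_fit",
    "rt_summaries",
    "skewness_g1",
    "neighborhood_rt_map",
]


def dprime(p_correct: float, p_error: float, n_trials: int) -> float:
    """Discriminability d' = Phi^-1(p_correct) - Phi^-1(p_error).

    Extreme proportions are clamped to [1/(2n), 1 - 1/(2n)] so that
    cells with perfect accuracy yield a finite value.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    lo, hi = 1.0 / (2 * n_trials), 1.0 - 1.0 / (2 * n_trials)
    pc = min(max(p_correct, lo), hi)
    pe = min(max(p_error, lo), hi)
    return float(sps.norm.ppf(pc) - sps.norm.ppf(pe))


def weibull_pc(c: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Weibull psychometric function %correct = 1 - 0.5 exp(-(c/alpha)^beta).

    ``c`` and ``alpha`` share units (coherence or contrast, in percent);
    the chance level at c = 0 is 0.5 for any parameters.
    """
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        out = 1.0 - 0.5 * np.exp(-np.power(np.where(c > 0, c / alpha, 0.0), beta))
    return np.where(c > 0, out, 0.5)


@dataclass
class WeibullFit:
    alpha: float  # threshold parameter (stimulus strength at ~81.6% correct)
    beta: float  # slope parameter
    residual_ss: float
    n_points: int

    def predict(self, c: np.ndarray) -> np.ndarray:
        return weibull_pc(c, self.alpha, self.beta)


def fit_weibull(
    c_values: np.ndarray,
    p_correct: np.ndarray,
    weights: np.ndarray | None = None,
) -> WeibullFit:
    """Least-squares Weibull fit of percent correct against stimulus strength.

    Unweighted by default; pass binomial weights (e.g. trial counts) for
    a weighted fit.  The c = 0 point carries no information about the
    parameters (its prediction is 0.5 identically) but is accepted.
    """
    c = np.asarray(c_values, dtype=float)
    p = np.asarray(p_correct, dtype=float)
    if (c > 0).sum() < 2:
        raise ValueError("need at least two distinct positive stimulus strengths")
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, dtype=float))
    alpha0 = float(np.median(c[c > 0]))
    try:
        popt, _ = optimize.curve_fit(
            weibull_pc, c, p, p0=[alpha0, 1.3], sigma=sigma,
            bounds=([1e-6, 1e-3], [np.inf, 20.0]), maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Weibull fit did not converge: {err}") from err
    resid = p - weibull_pc(c, *popt)
    return WeibullFit(alpha=float(popt[0]), beta=float(popt[1]), residual_ss=float(resid @ resid), n_points=len(c))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    t_statistic: float
    p_value: float
    bootstrap_mean: float
    bootstrap_sd: float
    ci_low: float
    ci_high: float
    n_boot: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def ols_slope_boot(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10_000,
    rng: np.random.Generator | int | None = None,
    ci: float = 0.95,
) -> RegressionResult:
    """OLS slope with t-statistic and a percentile case-resampling bootstrap.

    The point estimate, t and p come from the closed-form normal
    equations (via statsmodels); the bootstrap resamples (x, y) pairs
    with replacement ``n_boot`` times and reports the percentile
    confidence interval of the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slopes = np.empty(n_boot)
    n = x.size
    chunk = max(1, min(n_boot, int(5e6 / n)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        xs, ys = x[idx], y[idx]
        xm = xs.mean(axis=1, keepdims=True)
        ym = ys.mean(axis=1, keepdims=True)
        num = ((xs - xm) * (ys - ym)).sum(axis=1)
        den = ((xs - xm) ** 2).sum(axis=1)
        slopes[done : done + b] = num / den
        done += b
    alpha_tail = (1.0 - ci) / 2.0
    lo, hi = np.quantile(slopes, [alpha_tail, 1.0 - alpha_tail])
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        t_statistic=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        bootstrap_mean=float(slopes.mean()),
        bootstrap_sd=float(slopes.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


def probit_fit(outcomes: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood probit of a binary outcome on ``x`` with intercept.

    Returns (coefficient, t).  Raises if only one outcome class is
    present or if the classes are perfectly separated along ``x``.
    """
    y = np.asarray(outcomes, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.min(x[y == 1]) > np.max(x[y == 0]) or np.max(x[y == 1]) < np.min(x[y == 0]):
        raise ValueError("perfect separation along the covariate")
    model = sm.Probit(y, sm.add_constant(x)).fit(disp=0)
    return float(model.params[1]), float(model.tvalues[1])


def skewness_g1(values: np.ndarray) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) (biased moment estimator)."""
    v = np.asarray(values, dtype=float)
    d = v - v.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        return 0.0
    return float(np.mean(d**3) / m2**1.5)


@dataclass
class RTSummary:
    """Per-cell reaction-time summaries.

    The median and the error-minus-correct mean difference are computed
    on the deadline-censored subset; the SD/mean ratio and the skewness
    use the uncensored subset (no upper RT cut), mirroring how each
    panel of the behavioral analysis treats exclusions.
    """

    median_rt: float
    rt_diff_ec: float | None  # mean RT(error) - mean RT(correct)
    sd_mean_ratio: float
    skewness: float
    n_correct: int
    n_error: int


def rt_summaries(
    rt_censored_correct: np.ndarray,
    rt_censored_error: np.ndarray,
    rt_uncensored: np.ndarray,
) -> RTSummary:
    """Summaries from already-partitioned RT lists (ms)."""
    cens = np.concatenate([rt_censored_correct, rt_censored_error])
    med = float(np.median(cens)) if cens.size else float("nan")
    if rt_censored_correct.size and rt_censored_error.size:
        diff = float(np.mean(rt_censored_error) - np.mean(rt_censored_correct))
    else:
        diff = None
    unc = np.asarray(rt_uncensored, dtype=float)
    ratio = float(unc.std(ddof=0) / unc.mean()) if unc.size else float("nan")
    return RTSummary(
        median_rt=med,
        rt_diff_ec=diff,
        sd_mean_ratio=ratio,
        skewness=skewness_g1(unc) if unc.size else float("nan"),
        n_correct=int(rt_censored_correct.size),
        n_error=int(rt_censored_error.size),
    )


@dataclass
class NeighborhoodProbe:
    lambda_A: float
    lambda_B: float
    half_width: float
    n_errors: int
    rt_diff_ec: float  # mean RT(error) - mean RT(correct) inside the neighborhood
    reverse: bool  # True when errors are faster than correct decisions


def neighborhood_rt_map(
    table: pd.DataFrame,
    probes: np.ndarray | int = 400,
    rng: np.random.Generator | int | None = None,
    max_half_width: float = 2.5,
    min_errors: int = 50,
    step: float = 0.05,
    input_range: tuple[float, float] = (0.0, 20.0),
) -> tuple[list[NeighborhoodProbe], float]:
    """Classify the sign of the error-correct RT difference over input space.

    For each probe point (lambda_A, lambda_B), a square neighborhood is
    grown symmetrically (up to ``max_half_width``) until it contains at
    least ``min_errors`` erroneous decisions; probes that never reach
    the error quota are unreported.  Returns the classified probes and
    the mean attained half-width.

    The table must carry columns ``lambda_A``, ``lambda_B``, ``decided``,
    ``correct`` and ``rt_ms`` (from the input-space Monte-Carlo study).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if isinstance(probes, int):
        probes = rng.uniform(input_range[0], input_range[1], size=(probes, 2))
    dec = table[table["decided"]]
    la = dec["lambda_A"].to_numpy(float)
    lb = dec["lambda_B"].to_numpy(float)
    corr = dec["correct"].to_numpy(bool)
    rt = dec["rt_ms"].to_numpy(float)
    out: list[NeighborhoodProbe] = []
    widths = []
    for pa, pb in np.asarray(probes, dtype=float):
        h = step
        found = None
        while h <= max_half_width + 1e-9:
            inside = (np.abs(la - pa) <= h) & (np.abs(lb - pb) <= h)
            n_err = int((inside & ~corr).sum())
            if n_err >= min_errors:
                found = h
                break
            h += step
        if found is None:
            continue
        inside = (np.abs(la - pa) <= found) & (np.abs(lb - pb) <= found)
        err_rt = rt[inside & ~corr]
        cor_rt = rt[inside & corr]
        if cor_rt.size == 0:
            continue
        diff = float(err_rt.mean() - cor_rt.mean())
        out.append(
            NeighborhoodProbe(
                lambda_A=float(pa), lambda_B=float(pb), half_width=float(found),
                n_errors=int(err_rt.size), rt_diff_ec=diff, reverse=diff < 0,
            )
        )
        widths.append(found)
    mean_width = float(np.mean(widths)) if widths else float("nan")
    return out, mean_width
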
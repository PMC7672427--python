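"""Dose-response modeling and hypothesis testing.

Relates hairpin thermodynamics to expression output: linear and
4-parameter-logistic fits of fold change against fold free energy,
GC-class pair differentials, cross-host correlations, segmented
(plateau) analysis of helper-factor dose response, and the
Levene -> one-way ANOVA -> Dunnett testing chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "StatConfig",
    "fit_linear",
    "fit_logistic4",
    "predict_fc",
    "gc_pair_differential",
    "cross_correlation",
    "segmented_response",
    "anova_dunnett",
    "significance_flag",
]


@dataclass
class FitResult:
    model: str                       # "linear" or "logistic4"
    params: dict
    r2: float
    residuals: np.ndarray
    x_range: tuple = None

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            return self.params["intercept"] + self.params["slope"] * x
        if self.model == "logistic4":
            return _logistic4(x, self.params["a"], self.params["d"],
                              self.params["g50"], self.params["b"])
        raise ValueError(f"unknown model {self.model!r}")


def _r2(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    sst = ((y - y.mean()) ** 2).sum()
    sse = ((y - yhat) ** 2).sum()
    if sst == 0:
        return 1.0 if sse == 0 else 0.0
    return float(max(0.0, min(1.0, 1.0 - sse / sst)))


def fit_linear(x, y) -> FitResult:
    """Ordinary least squares of y on x with R^2 = 1 - SSE/SST."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x is constant")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    return FitResult("linear",
                     {"slope": float(res.slope), "intercept": float(res.intercept)},
                     _r2(y, yhat), y - yhat, (float(x.min()), float(x.max())))


def _logistic4(x, a, d, g50, b):
    z = np.clip((np.asarray(x, dtype=float) - g50) / b, -500.0, 500.0)
    return d + (a - d) / (1.0 + np.exp(z))


def fit_logistic4(x, y) -> FitResult:
    """4-parameter logistic fc(dG) = d + (a-d)/(1+exp((dG-g50)/b)).

    Least squares with multistart: g50 over the x quantiles, several
    slope widths including a near-linear (very shallow) start, so the
    fit never does worse than whatever start converges best.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 5:
        raise ValueError("need at least 5 points")
    span = np.ptp(x)
    if span == 0:
        raise ValueError("degenerate predictor: x is constant")
    lo, hi = float(y.min()), float(y.max())
    pad = 0.1 * (hi - lo) if hi > lo else 0.1
    best = None
    for g50 in np.quantile(x, [0.2, 0.35, 0.5, 0.65, 0.8]):
        for b in (span / 20, span / 8, span / 3, span * 5):
            p0 = (hi + pad, lo - pad, float(g50), float(b))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    popt, _ = optimize.curve_fit(_logistic4, x, y, p0=p0,
                                                 maxfev=20000)
            except RuntimeError:
                continue
            resid = y - _logistic4(x, *popt)
            sse = float((resid ** 2).sum())
            if not np.isfinite(sse):
                continue
            if best is None or sse < best[0]:
                best = (sse, popt, resid)
    if best is None:
        raise RuntimeError("logistic fit did not converge from any start")
    _, popt, resid = best
    params = dict(zip(("a", "d", "g50", "b"), (float(v) for v in popt)))
    return FitResult("logistic4", params, _r2(y, y - resid), resid,
                     (float(x.min()), float(x.max())))


def predict_fc(fit: FitResult, dg):
    """Evaluate a fitted model; warns when extrapolating beyond the data."""
    if not isinstance(fit, FitResult):
        raise ValueError("predict_fc requires a fitted model")
    dg_arr = np.atleast_1d(np.asarray(dg, dtype=float))
    if fit.x_range is not None:
        lo, hi = fit.x_range
        if ((dg_arr < lo) | (dg_arr > hi)).any():
            warnings.warn("prediction extrapolates beyond the fitted dG range")
    out = fit.predict(dg_arr)
    return float(out[0]) if np.isscalar(dg) or np.ndim(dg) == 0 else out


def gc_pair_differential(pairs, exclusions=()) -> pd.DataFrame:
    """Fold-change differential between matched high- and low-GC elements.

    ``pairs`` maps a pair label -> (fc_high_gc, fc_low_gc); the
    differential is fc_high - fc_low, so stronger repression by the
    high-GC member gives a negative value.  Excluded pairs stay in the
    per-pair output but are left out of the mean (``in_mean`` column;
    the mean itself is in ``df.attrs['mean_diff']``).
    """
    if isinstance(pairs, dict):
        items = list(pairs.items())
    else:
        items = [(f"pair{i}", p) for i, p in enumerate(pairs)]
    if not items:
        raise ValueError("no pairs supplied")
    rows = [{"pair": k, "fc_high": float(h), "fc_low": float(l),
             "diff": float(h) - float(l), "in_mean": k not in set(exclusions)}
            for k, (h, l) in items]
    df = pd.DataFrame(rows)
    kept = df.loc[df["in_mean"], "diff"]
    if len(kept) == 0:
        raise ValueError("all pairs excluded from the mean")
    df.attrs["mean_diff"] = float(kept.mean())
    return df


def cross_correlation(x_fc, y_fc) -> FitResult:
    """OLS relation between two matched fold-change vectors (with R^2)."""
    x = np.asarray(x_fc, dtype=float)
    y = np.asarray(y_fc, dtype=float)
    if len(x) != len(y):
        raise ValueError("fold-change vectors have different lengths")
    return fit_linear(x, y)


def segmented_response(level, response, split=0.4):
    """Dose-response analysis with a plateau breakpoint.

    Fixed-split mode (``split`` numeric): OLS + R^2 within the
    low (< split) and high (> split) groups.  Estimate mode
    (``split='estimate'``): grid search over candidate breakpoints
    (observed levels plus 100 uniform points) minimizing the SSE of the
    continuous plateau model ``response = c * min(level, tau) / tau``.
    """
    level = np.asarray(level, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(level) != len(response):
        raise ValueError("level and response lengths differ")
    if isinstance(split, str):
        if split != "estimate":
            raise ValueError("split must be a number or 'estimate'")
        if len(level) < 6:
            raise ValueError("breakpoint estimation needs at least 6 points")
        candidates = np.unique(np.concatenate(
            [level, np.linspace(level.min(), level.max(), 100)]))
        candidates = candidates[candidates > 0]
        best = None
        for tau in candidates:
            xs = np.minimum(level, tau) / tau
            denom = (xs ** 2).sum()
            c = (response * xs).sum() / denom if denom > 0 else 0.0
            sse = (((response - c * xs) ** 2).sum())
            if best is None or sse < best[0] - 1e-12:
                best = (sse, float(tau), float(c))
        sse, tau, c = best
        return {"breakpoint": tau, "plateau": c, "sse": sse}
    split = float(split)
    low = level < split
    high = level > split
    if low.sum() == 0 or high.sum() == 0:
        raise ValueError(f"one group empty at split {split}")
    return {"split": split,
            "low": fit_linear(level[low], response[low]),
            "high": fit_linear(level[high], response[high])}


# ---------------------------------------------------------------------------
# hypothesis testing chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    control_name: str = "CMV"
    variance_check: str = "levene"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def significance_flag(p: float, alpha: float = 0.05) -> str:
    """Study notation: n.s. / # (<0.1) / * (<alpha) / ** (<0.01) / *** (<0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    if p < 0.1:
        return "#"
    return "n.s."


def anova_dunnett(groups: dict, config: StatConfig = StatConfig()) -> dict:
    """Levene -> one-way ANOVA -> Dunnett many-to-one chain.

    ``groups`` maps group name -> replicate values; the control group is
    named in the config.  Returns Levene and ANOVA p-values plus a
    per-group table of Dunnett-adjusted p-values and significance flags.
    """
    if config.control_name not in groups:
        raise ValueError(f"control group {config.control_name!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 replicates")
    control = arrays[config.control_name]
    others = [k for k in arrays if k != config.control_name]

    levene_p = float(stats.levene(*arrays.values()).pvalue)
    anova = stats.f_oneway(*arrays.values())
    dunnett = stats.dunnett(*[arrays[k] for k in others], control=control,
                            random_state=np.random.default_rng(12345))
    rows = [{"group": k, "p_value": float(p),
             "significant": bool(p < config.alpha),
             "flag": significance_flag(float(p), config.alpha)}
            for k, p in zip(others, dunnett.pvalue)]
    return {"levene_p": levene_p, "anova_f": float(anova.statistic),
            "anova_p": float(anova.pvalue), "comparisons": pd.DataFrame(rows)}
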
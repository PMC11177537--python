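"""Spousal-correlation estimation and the statistics around it: Fisher-z
comparison of correlations across strata, Bonferroni thresholds, the
Fisher-z power/sample-size rule, variance-explained (adjusted R²) models
and residualized re-correlation.

Quantitative trait correlations between spouses use Spearman's rank
correlation; ancestry-PC and polygenic-score correlations use Pearson.
Confidence intervals use the Fisher z transform (an approximation for
Spearman, labeled as such in output).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class CorrelationError(ValueError):
    pass


class DegenerateInputError(ValueError):
    """Residuals (or inputs) are constant; a correlation is undefined."""


@dataclass
class SpousalCorr:
    variable: str
    method: str               # pearson / spearman
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    stratum: str = "all"
    ci_method: str = "fisher_z"


@dataclass
class CorrComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    denom = np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    if denom == 0:
        raise DegenerateInputError("constant ranks")
    count = 0
    total = 0
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    for perm in itertools.permutations(range(n)):
        rho = (rxc * ryc[list(perm)]).sum() / denom
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spousal_correlation(father_values, mother_values, method: str = "spearman",
                        variable: str = "", stratum: str = "all") -> SpousalCorr:
    """Correlation between spouses over pairwise-complete pairs.

    Pearson p-values use the t distribution; Spearman p-values use exact
    permutation enumeration for n <= 8 and the t approximation above.
    """
    x = np.asarray(father_values, dtype=float)
    y = np.asarray(mother_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise CorrelationError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant values; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
        if n <= 8:
            p = _spearman_exact_p(x, y, r)
    else:
        raise ValueError(f"unknown method {method}")
    lo, hi = _fisher_ci(r, n)
    return SpousalCorr(variable, method, float(r), n, lo, hi, float(p), stratum)


def compare_correlations(c1: SpousalCorr, c2: SpousalCorr) -> CorrComparison:
    """Fisher z-test for two correlations from independent strata:
    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))."""
    if c1.n <= 3 or c2.n <= 3:
        raise CorrelationError("both strata need n > 3")
    z = (np.arctanh(c1.r) - np.arctanh(c2.r)) / np.sqrt(
        1.0 / (c1.n - 3) + 1.0 / (c2.n - 3))
    p = 2 * stats.norm.sf(abs(z))
    return CorrComparison(c1.r, c1.n, c2.r, c2.n, float(z), float(p))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def min_n_for_power(r: float, alpha: float = 0.05, power: float = 0.8) -> int:
    """Smallest n giving the target power to detect correlation r (two-sided).

    Fisher-z approximation: n = ceil(((z_{1-a/2} + z_power) / atanh(r))^2 + 3).
    """
    if not (0 < r < 1):
        raise ValueError("r must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return int(np.ceil(((z_a + z_b) / np.arctanh(r)) ** 2 + 3))


def empirical_power(n: int, r: float, alpha: float = 0.05,
                    n_reps: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo power of the Pearson test at sample size n, true correlation r.

    Draws ``n_reps`` bivariate-normal samples, tests each correlation
    against zero at two-sided ``alpha``, and returns the rejection
    fraction.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_reps, n))
    e = rng.standard_normal((n_reps, n))
    y = r * x + np.sqrt(1 - r * r) * e
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    rhat = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    t = rhat * np.sqrt((n - 2) / (1 - rhat**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return float((p < alpha).mean())


def comparison_type1_error(n_pairs: int = 200, rho: float = 0.3,
                           n_reps: int = 1000, alpha: float = 0.05,
                           seed: int = 0) -> float:
    """Type-I error of the Fisher-z comparison under exchangeable strata.

    Each replicate draws one set of bivariate-normal spousal pairs with a
    common correlation, splits it by an exchangeable random label into two
    strata, and tests the strata correlations for difference; the true
    difference is zero by construction.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.standard_normal(2 * n_pairs)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(2 * n_pairs)
        labels = rng.permutation(np.repeat([0, 1], n_pairs))
        cs = []
        for g in (0, 1):
            m = labels == g
            cs.append(spousal_correlation(x[m], y[m], method="pearson"))
        if compare_correlations(cs[0], cs[1]).p < alpha:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# Variance explained and residualized correlations
# ---------------------------------------------------------------------------

def _ols_adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    n, p = X.shape
    if n <= p + 1:
        raise CorrelationError(f"n={n} too small for {p} predictors")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return float(fit.rsquared_adj)


def variance_explained(trait_values: np.ndarray,
                       predictor_blocks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Adjusted R² of the trait on each predictor block plus the full model.

    Each block is an (n,) or (n, p) array (e.g. sex, age, education, the
    top-10 PCs jointly, each polygenic score).  Rows with any missing
    value are dropped listwise within each model.
    """
    y = np.asarray(trait_values, dtype=float)
    rows = []
    blocks = {k: np.atleast_2d(np.asarray(v, dtype=float).T).T for k, v in predictor_blocks.items()}
    for name, X in blocks.items():
        ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
        rows.append({"model": name, "adjusted_r2": _ols_adjusted_r2(y[ok], X[ok]),
                     "n": int(ok.sum())})
    X_full = np.column_stack(list(blocks.values()))
    ok = np.isfinite(y) & np.isfinite(X_full).all(axis=1)
    rows.append({"model": "full", "adjusted_r2": _ols_adjusted_r2(y[ok], X_full[ok]),
                 "n": int(ok.sum())})
    return pd.DataFrame(rows)


def residualized_spousal_correlation(
    father_values, mother_values,
    father_block: np.ndarray, mother_block: np.ndarray,
    method: str = "spearman", variable: str = "",
) -> pd.DataFrame:
    """Spousal correlation before and after residualizing on a covariate block.

    The OLS residualization is fitted on all parents jointly (fathers and
    mothers stacked); the block must exclude sex, which is confounded with
    the spousal pairing itself.  Returns r_raw, r_residual and the
    fractional change (r_raw - r_residual) / r_raw.
    """
    fx = np.asarray(father_values, dtype=float)
    mx = np.asarray(mother_values, dtype=float)
    fb = np.atleast_2d(np.asarray(father_block, dtype=float).T).T
    mb = np.atleast_2d(np.asarray(mother_block, dtype=float).T).T

    raw = spousal_correlation(fx, mx, method=method, variable=variable)

    y = np.concatenate([fx, mx])
    X = np.vstack([fb, mb])
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    fit = sm.OLS(y[ok], sm.add_constant(X[ok])).fit()
    resid = np.full(len(y), np.nan)
    resid[ok] = y[ok] - fit.predict(sm.add_constant(X[ok]))
    rf, rm = resid[: len(fx)], resid[len(fx):]
    if np.nanstd(rf) < 1e-12 or np.nanstd(rm) < 1e-12:
        raise DegenerateInputError("residuals are (near) constant; correlation undefined")
    res = spousal_correlation(rf, rm, method=method, variable=f"{variable}_residual")

    frac = (raw.r - res.r) / raw.r if raw.r != 0 else float("nan")
    return pd.DataFrame([{
        "variable": variable, "method": method,
        "r_raw": raw.r, "p_raw": raw.p, "n_raw": raw.n,
        "r_residual": res.r, "p_residual": res.p, "n_residual": res.n,
        "fractional_change": frac,
    }])
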
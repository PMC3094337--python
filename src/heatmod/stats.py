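"""Hypothesis tests, p-value combination and multiple-testing correction.

This is the pure computational kernel the analysis engines call:

* Fisher's exact test on a 2x2 table (hypergeometric tails, two-sided by
  the minimum-likelihood rule),
* the exact binomial test,
* a z-score test whose null distribution is built by resampling random
  gene sets of the same size from the column background,
* Whitlock's weighted Z-method for combining independent p-values,
* Pearson correlation with a t-distribution p-value,
* Holm and Benjamini-Hochberg p-value adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .matrix import DataError, TestConfig

__all__ = [
    "TestResult",
    "CombineConfig",
    "fisher_exact",
    "binomial_exact",
    "zscore_bootstrap",
    "weighted_z_combine",
    "pearson",
    "adjust_pvalues",
]

#: clamp for p-values before the normal quantile transform
P_EPS = 1e-15


@dataclass
class TestResult:
    """Statistics produced by one hypothesis test on one (unit, condition)
    pair: observed and expected value, z-score (when defined) and the
    left / right / two-sided tail p-values."""

    observed: float
    expected: float
    z: float | None
    p_left: float
    p_right: float
    p_two: float
    n_module: int
    note: str | None = None

    def __post_init__(self):
        for name in ("p_left", "p_right", "p_two"):
            p = getattr(self, name)
            if not (math.isnan(p) or -1e-12 <= p <= 1 + 1e-12):
                raise DataError(f"{name}={p} outside [0, 1]")
            setattr(self, name, float(min(1.0, max(0.0, p))))
        if self.n_module < 0:
            raise DataError("n_module must be >= 0")


@dataclass
class CombineConfig:
    """How to weight the inputs of a weighted-Z combination.

    ``uniform`` gives every p-value the same weight; ``sqrt_n`` uses the
    square root of each input's sample size (Whitlock's recommendation when
    studies differ in size); ``user`` takes explicit weights.
    """

    weight_mode: str = "uniform"            # uniform | sqrt_n | user
    weights: list[float] | None = None

    def __post_init__(self):
        if self.weight_mode not in ("uniform", "sqrt_n", "user"):
            raise DataError(f"unknown weight mode {self.weight_mode!r}")
        if self.weight_mode == "user":
            if not self.weights or all(w == 0 for w in self.weights):
                raise DataError("user weights need at least one positive value")
            if any(w < 0 for w in self.weights):
                raise DataError("weights must be nonnegative")


def fisher_exact(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher's exact test for the 2x2 table [[a, b], [c, d]].

    Row 1 is the module (a events, b non-events), row 2 the rest of the
    universe.  ``p_right`` is P(X >= a) under the hypergeometric law with
    fixed margins (over-representation), ``p_left`` is P(X <= a), and
    ``p_two`` sums the probabilities of all tables as or less likely than
    the observed one.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise DataError("table counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0:
        return TestResult(0.0, 0.0, None, 1.0, 1.0, 1.0, 0, note="empty table")
    hg = sps.hypergeom(n_total, col1, row1)
    p_right = float(hg.sf(a - 1))
    p_left = float(hg.cdf(a))
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hg.pmf(support)
    # minimum-likelihood two-sided rule, with slack for floating pmf ties
    p_two = float(pmf[pmf <= pmf[support == a][0] * (1 + 1e-7)].sum())
    expected = row1 * col1 / n_total
    return TestResult(float(a), expected, None,
                      min(1.0, p_left), min(1.0, p_right), min(1.0, p_two), row1)


def binomial_exact(k: int, n: int, p0: float) -> TestResult:
    """Exact binomial test of k successes in n trials against rate ``p0``.

    ``p_right`` = P(X >= k), ``p_left`` = P(X <= k); the two-sided value is
    twice the smaller tail, capped at 1.
    """
    if not (0 <= p0 <= 1):
        raise DataError("p0 must be in [0, 1]")
    if not (0 <= k <= n):
        raise DataError("need 0 <= k <= n")
    k, n = int(k), int(n)
    bn = sps.binom(n, p0)
    p_right = float(bn.sf(k - 1))
    p_left = float(bn.cdf(k))
    p_two = min(1.0, 2.0 * min(p_left, p_right))
    z = None
    var = n * p0 * (1 - p0)
    if var > 0:
        z = (k - n * p0) / math.sqrt(var)
    return TestResult(float(k), n * p0, z,
                      min(1.0, p_left), min(1.0, p_right), p_two, n)


def _bootstrap_statistics(background: np.ndarray, n: int, iterations: int,
                          statistic: str, rng: np.random.Generator,
                          with_replacement: bool) -> np.ndarray:
    """Statistics of ``iterations`` random size-``n`` draws from the
    background (the null: a random gene set of the same size)."""
    stat = np.mean if statistic == "mean" else np.median
    N = background.size
    if with_replacement:
        idx = rng.integers(0, N, size=(iterations, n))
        return stat(background[idx], axis=1)
    if n == N:
        # the only size-N subset is the background itself
        return np.full(iterations, float(stat(background)))
    # without replacement: order-statistics trick — the n smallest random
    # keys of each iteration index a uniform random subset of size n
    keys = rng.random((iterations, N))
    idx = np.argpartition(keys, n, axis=1)[:, :n]
    return stat(background[idx], axis=1)


def zscore_bootstrap(module_values, background, cfg: TestConfig,
                     rng: np.random.Generator | None = None) -> TestResult:
    """Z-score test with a resampling null for "random gene set".

    The observed statistic (mean or median of the module's values) is
    compared against the distribution of the same statistic over B random
    draws of the same size from the column background.  The z-score is
    referred to the standard normal for tail p-values.
    """
    module_values = np.asarray(module_values, dtype=float)
    background = np.asarray(background, dtype=float)
    module_values = module_values[~np.isnan(module_values)]
    background = background[~np.isnan(background)]
    n = module_values.size
    if n == 0 or background.size == 0:
        raise DataError("empty module or background")
    if n > background.size and not cfg.with_replacement:
        raise DataError("module larger than background")
    if rng is None:
        if cfg.seed is None:
            raise DataError("zscore_bootstrap requires an explicit seed")
        rng = np.random.default_rng(cfg.seed)
    stat = np.mean if cfg.statistic == "mean" else np.median
    observed = float(stat(module_values))
    boots = _bootstrap_statistics(background, n, cfg.bootstrap_iterations,
                                  cfg.statistic, rng, cfg.with_replacement)
    mu = float(np.mean(boots))
    sd = float(np.std(boots, ddof=1)) if boots.size > 1 else 0.0
    if sd <= 1e-12 * (abs(mu) + 1.0):  # constant resamples up to float error
        return TestResult(observed, mu, 0.0, 1.0, 1.0, 1.0, n,
                          note="degenerate bootstrap (sd = 0)")
    z = (observed - mu) / sd
    p_right = float(sps.norm.sf(z))
    p_left = float(sps.norm.cdf(z))
    p_two = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(observed, mu, z, p_left, p_right, min(1.0, p_two), n)


def weighted_z_combine(pvalues, weights=None) -> tuple[float, float, int]:
    """Combine independent one-sided p-values by the weighted Z-method.

    z_i = Phi^-1(1 - p_i);  Z = sum(w_i z_i) / sqrt(sum(w_i^2));
    combined p = 1 - Phi(Z).  Missing p-values are dropped together with
    their weights.  Returns ``(combined_p, Z, n_used)``; all-missing input
    yields ``(nan, nan, 0)``.
    """
    p = np.asarray(pvalues, dtype=float)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise DataError("weights must match pvalues in length")
        if (w < 0).any():
            raise DataError("weights must be nonnegative")
    keep = ~np.isnan(p) & ~np.isnan(w)
    p, w = p[keep], w[keep]
    if p.size == 0:
        return (float("nan"), float("nan"), 0)
    if not (w > 0).any():
        raise DataError("at least one positive weight required")
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must be in [0, 1]")
    p = np.clip(p, P_EPS, 1 - P_EPS)
    z = sps.norm.isf(p)              # Phi^-1(1 - p)
    Z = float(np.sum(w * z) / math.sqrt(float(np.sum(w * w))))
    return (float(sps.norm.sf(Z)), Z, int(p.size))


def pearson(x, y) -> dict:
    """Pearson correlation on pairwise-complete observations.

    Returns ``{"r", "n", "p_two"}``; the p-value comes from the
    t-distribution with n-2 degrees of freedom.  Fewer than 3 complete
    pairs, or zero variance in either vector, yields a missing ``r`` with
    an explanatory note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must have equal length")
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        return {"r": float("nan"), "n": n, "p_two": float("nan"),
                "note": "fewer than 3 complete pairs"}
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": float("nan"), "n": n, "p_two": float("nan"),
                "note": "zero variance"}
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return {"r": r, "n": n, "p_two": p, "note": None}


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Holm (step-down) or Benjamini-Hochberg (step-up) adjusted p-values.

    Missing entries are excluded from the family size m and returned as
    missing; original order is restored.
    """
    if method not in ("holm", "bh"):
        raise DataError(f"unknown correction method {method!r}")
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    keep = ~np.isnan(p)
    obs = p[keep]
    if ((obs < 0) | (obs > 1)).any():
        raise DataError("p-values must be in [0, 1]")
    if obs.size:
        sm_method = "holm" if method == "holm" else "fdr_bh"
        out[keep] = multipletests(obs, method=sm_method)[1]
    return out
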
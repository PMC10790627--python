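"""Circular and resampling statistics shared across pipeline stages.

Rayleigh test for non-uniform circular samples, a two-sample Kuiper test
for comparing circular distributions, the common-language effect size
(CLES), Benjamini-Hochberg FDR control, and the Monte-Carlo permutation
test on median differences used by the connectivity analysis.  Standard
location tests (Mann-Whitney, t, Wilcoxon, Shapiro-Wilk) are delegated to
scipy/pingouin directly by callers and are not wrapped here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pingouin
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    """Statistic, p value, per-group sample sizes, and method tag."""

    statistic: float
    pvalue: float
    n: tuple
    method: str

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"pvalue out of [0, 1]: {self.pvalue}")


def rayleigh_test(phases) -> TestResult:
    """Rayleigh test of circular uniformity.

    Z = N * Rbar^2 with the standard small-sample-corrected p
    approximation.  Requires N >= 5.
    """
    phases = np.asarray(phases, dtype=float).ravel()
    n = phases.size
    if n < 5:
        raise ValueError(f"rayleigh_test requires N >= 5, got {n}")
    z, p = pingouin.circ_rayleigh(phases)
    return TestResult(float(z), float(min(max(p, 0.0), 1.0)), (n,), "rayleigh")


def _kuiper_fpp(v: float, n_eff: float) -> float:
    """Asymptotic upper-tail probability of the Kuiper statistic.

    Uses the standard series with the Stephens finite-sample correction
    lambda = (sqrt(N) + 0.155 + 0.24/sqrt(N)) * V.
    """
    if v <= 0:
        return 1.0
    lam = (np.sqrt(n_eff) + 0.155 + 0.24 / np.sqrt(n_eff)) * v
    if lam < 0.4:
        return 1.0
    j = np.arange(1, 101, dtype=float)
    terms = (4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2)
    p = 2.0 * terms.sum()
    return float(min(max(p, 0.0), 1.0))


def kuiper_two_sample(phases_a, phases_b) -> TestResult:
    """Two-sample Kuiper test for circular distributions.

    V = D+ + D- between the two empirical CDFs; V is invariant under a
    common rotation of both samples, which is what makes the test
    appropriate on the circle.  p value from the asymptotic series with
    effective size n_a*n_b/(n_a+n_b).
    """
    a = np.sort(np.asarray(phases_a, dtype=float).ravel())
    b = np.sort(np.asarray(phases_b, dtype=float).ravel())
    na, nb = a.size, b.size
    if na < 5 or nb < 5:
        raise ValueError(f"kuiper_two_sample requires N >= 5 per sample, got ({na}, {nb})")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / na
    cdf_b = np.searchsorted(b, grid, side="right") / nb
    d = cdf_a - cdf_b
    v = float(d.max() - d.min())
    n_eff = na * nb / (na + nb)
    return TestResult(v, _kuiper_fpp(v, n_eff), (na, nb), "kuiper-2samp")


def cles(x, y) -> float:
    """Common-language effect size: P(X > Y) + 0.5 * P(X = Y).

    Equals U / (n1 * n2) for the Mann-Whitney U of x vs y.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("cles requires nonempty samples")
    diff = x[:, None] - y[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / diff.size)


def fdr_bh(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p values); adjusted p values are
    monotone non-decreasing in the rank of the raw p value.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def perm_test_median_diff(weights_a, weights_b, n_iter: int = 10_000, seed=None) -> TestResult:
    """Two-sided Monte-Carlo permutation test on the difference of medians.

    The observed statistic is median(a) - median(b); the null is built by
    relabeling the pooled values into groups of the original sizes.  The
    add-one estimator p = (1 + #{|null| >= |obs|}) / (1 + n_iter) keeps p
    strictly positive.
    """
    a = np.asarray(weights_a, dtype=float).ravel()
    b = np.asarray(weights_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is small; p estimate will be coarse")
    rng = np.random.default_rng(seed)
    obs = float(np.median(a) - np.median(b))
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    # vectorized batch permutations to bound memory
    count = 0
    batch = max(1, min(n_iter, int(4e7 // max(n, 1))))
    done = 0
    while done < n_iter:
        m = min(batch, n_iter - done)
        keys = rng.random((m, n))
        order = np.argsort(keys, axis=1)
        perm = pooled[order]
        null = np.median(perm[:, :na], axis=1) - np.median(perm[:, na:], axis=1)
        count += int(np.count_nonzero(np.abs(null) >= abs(obs) - 1e-12))
        done += m
    p = (1.0 + count) / (1.0 + n_iter)
    return TestResult(obs, float(min(p, 1.0)), (na, b.size), "perm-median-diff")
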
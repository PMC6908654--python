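"""Nonparametric cohort statistics on the per-eye, per-region metrics.

Void-area percentages are not normally distributed, so after a
Shapiro-Wilk normality check the group comparison is the two-sided
Mann-Whitney U test, correlation with choroidal thickness is Spearman's
rho, and between-session reproducibility is a one-way ANOVA with session
as the factor.  All tests are thin, contract-checked wrappers around
scipy.stats; the Mann-Whitney exact small-sample path is cross-checked
in the test suite against a full enumeration oracle.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .scan_model import ContractError

__all__ = [
    "mann_whitney",
    "shapiro_wilk",
    "spearman",
    "repeatability_anova",
    "power_simulation",
]

#: Largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated (no-ties case).
_EXACT_N_MAX = 12


def _as_sample(x, name: str, min_n: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < min_n:
        raise ContractError(f"sample {name!r} needs at least {min_n} values, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ContractError(f"sample {name!r} contains non-finite values")
    return x


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample ``a``, p).

    Uses the exact permutation null when the combined sample is small
    (<= 12) and tie-free, otherwise the normal approximation with tie
    correction and continuity correction.  Symmetric in p under group
    exchange.  Degenerate all-identical data yields p = 1.
    """
    a = _as_sample(a, "a")
    b = _as_sample(b, "b")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_N_MAX and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test (gates the nonparametric route)."""
    x = _as_sample(sample, "sample", min_n=3)
    if len(x) > 5000:
        raise ContractError("Shapiro-Wilk supports n <= 5000")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with two-sided p."""
    x = _as_sample(x, "x", min_n=3)
    y = _as_sample(y, "y", min_n=3)
    if len(x) != len(y):
        raise ContractError(f"length mismatch: {len(x)} vs {len(y)}")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def repeatability_anova(session1, session2) -> tuple[float, float]:
    """One-way ANOVA with imaging session as the factor; returns (F, p).

    Identical sessions give F = 0 (perfect reproducibility); a constant
    offset between sessions inflates the between-session mean square.
    """
    s1 = _as_sample(session1, "session1", min_n=2)
    s2 = _as_sample(session2, "session2", min_n=2)
    if len(s1) != len(s2):
        raise ContractError(f"length mismatch: {len(s1)} vs {len(s2)}")
    pooled = np.concatenate([s1, s2])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if s1.var(ddof=1) + s2.var(ddof=1) == 0.0:
        # no within-session variance: shifted constants separate perfectly
        return float("inf"), 0.0
    res = sps.f_oneway(s1, s2)
    return float(res.statistic), float(res.pvalue)


def power_simulation(
    delta_pct: float,
    sd_pct: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided Mann-Whitney comparison.

    Draws ``reps`` pairs of normal samples (percent scale) whose means
    differ by ``delta_pct`` with common spread ``sd_pct`` and returns the
    rejection fraction at level ``alpha``.  With ``delta_pct = 0`` this
    estimates the achieved type-I error.
    """
    if reps < 100:
        raise ContractError("reps must be >= 100 for a stable estimate")
    if sd_pct <= 0 or n1 < 2 or n2 < 2 or not (0 < alpha < 1):
        raise ContractError("invalid power-simulation parameters")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        a = rng.normal(0.0, sd_pct, n1)
        b = rng.normal(delta_pct, sd_pct, n2)
        _, p = mann_whitney(a, b)
        hits += p < alpha
    return hits / reps
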
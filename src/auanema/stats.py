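"""Nonparametric and goodness-of-fit statistics.

The Mann-Whitney U test here computes its exact two-sided p-value from the
tie-free null distribution of U (the classical distribution over all
C(n1+n2, n1) rank assignments), even when the observed samples contain ties.
Ties still enter the observed statistic (each tied cross-pair contributes
0.5), but the null is the standard tie-free one.  This is the convention of
R's ``wilcox.test`` exact path and is the one under which the RNAi sex-ratio
comparison of a 8-vs-9 mother experiment gives U = 67, p = 0.001563.

Kruskal-Wallis and the chi-square goodness-of-fit test are thin, validated
fronts over :mod:`scipy.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "exact_u_null_pmf",
    "kruskal_wallis",
    "chisq_gof",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic:
        U, H or X² depending on the test; always >= 0.
    p_value:
        Two-sided (U) or upper-tail (H, X²) p-value in [0, 1].
    method:
        ``"exact"`` only when the exact null enumeration was used;
        otherwise ``"normal_approx"`` or ``"chi2_approx"``.
    n_per_group:
        Sample size of each group, in input order.
    """

    statistic: float
    p_value: float
    method: Literal["exact", "normal_approx", "chi2_approx"]
    n_per_group: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.statistic < 0:
            raise ValueError(f"statistic {self.statistic} negative")


def _as_finite_1d(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"empty sample: {name}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")
    return arr


def exact_u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact tie-free null pmf of the Mann-Whitney U statistic.

    Returns an array ``p`` of length ``n1*n2 + 1`` with ``p[u] = P(U = u)``
    under random assignment of ranks 1..n1+n2 to the two groups.  Computed
    by the standard dynamic program over partial group assignments
    (O(n1 * n2 * (n1+n2)) time).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("empty sample")
    # f[j] holds the count array over U for (i, j) at the current i
    f: list[np.ndarray] = [np.array([1.0])] * (n2 + 1)
    for i in range(1, n1 + 1):
        g: list[np.ndarray] = [np.array([1.0])]
        for j in range(1, n2 + 1):
            a = np.zeros(i * j + 1)
            a[: i * (j - 1) + 1] += g[j - 1]  # largest obs is from group 2
            a[j:] += f[j]  # largest obs is from group 1: adds j to U
            g.append(a)
        f = g
    counts = f[n2]
    return counts / counts.sum()


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    less = (y[None, :] < x[:, None]).sum()
    tied = (y[None, :] == x[:, None]).sum()
    return float(less) + 0.5 * float(tied)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "normal"] = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test of x vs y.

    ``U = sum_i [#{y_j < x_i} + 0.5 * #{y_j = x_i}]``.  In exact mode the
    p-value is ``min(1, 2*min(P(U >= u), P(U <= u)))`` under the tie-free
    null (see module docstring); ties in the data contribute half counts to
    the observed U only.  ``auto`` picks exact when ``n1*n2 <= 400``, else
    the normal approximation with tie-corrected variance and a 0.5
    continuity correction.
    """
    xa = _as_finite_1d(x, "x")
    ya = _as_finite_1d(y, "y")
    n1, n2 = xa.size, ya.size
    u = _u_statistic(xa, ya)

    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n1 * n2 <= 400)

    if use_exact:
        pmf = exact_u_null_pmf(n1, n2)
        # observed U may be half-integral under ties; P(U >= u) over the
        # integer-supported null is unaffected by the half step direction
        # chosen here (ceil for the upper tail, floor for the lower).
        upper = pmf[int(np.ceil(u)) :].sum()
        lower = pmf[: int(np.floor(u)) + 1].sum()
        p = min(1.0, 2.0 * min(upper, lower))
        return TestResult(u, float(p), "exact", (n1, n2))

    # normal approximation, tie-corrected variance, continuity correction
    pooled = np.concatenate([xa, ya])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return TestResult(u, 1.0, "normal_approx", (n1, n2))
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return TestResult(u, float(p), "normal_approx", (n1, n2))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups.

    Midranks with tie correction; p from the chi-square approximation with
    ``len(groups) - 1`` degrees of freedom.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    arrays = [_as_finite_1d(g, f"group {i}") for i, g in enumerate(groups)]
    ns = tuple(a.size for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # all values identical: H = 0 by convention, no evidence
        return TestResult(0.0, 1.0, "chi2_approx", ns)
    h, p = sps.kruskal(*arrays)
    return TestResult(float(max(h, 0.0)), float(p), "chi2_approx", ns)


def chisq_gof(
    observed: Sequence[int], expected_prop: Sequence[float]
) -> TestResult:
    """Chi-square goodness of fit of observed counts to expected proportions."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_prop, dtype=float)
    if obs.ndim != 1 or obs.size < 2 or obs.size != props.size:
        raise ValueError("observed and expected_prop must have equal length >= 2")
    if np.any(obs < 0) or not np.all(obs == np.round(obs)):
        raise ValueError("observed must be nonnegative integers")
    total = obs.sum()
    if total < 1:
        raise ValueError("total observed count must be >= 1")
    if not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise ValueError("expected proportions must sum to 1")
    if np.any((props <= 0) & (obs > 0)):
        raise ValueError("expected proportion of 0 with nonzero observed count")
    keep = props > 0
    stat, p = sps.chisquare(obs[keep], total * props[keep])
    # df must reflect the original number of classes
    df = obs.size - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(float(stat), p, "chi2_approx", tuple(int(o) for o in obs))
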
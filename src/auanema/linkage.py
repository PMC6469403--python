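"""Genetic-map construction from an F2 intercross genotype matrix.

Marker filtering (duplicates and >= 50% missing), two-point recombination
fraction estimation by maximum likelihood under the co-dominant F2 model,
LOD-threshold linkage grouping, Kosambi map distances, greedy within-group
ordering, and a per-marker segregation-distortion scan.

The F2 likelihood assumes a standard intercross (both parents F1
heterozygotes in coupling).  Panels propagated beyond F2 by selfing violate
this mildly; grouping is robust to it but the distances are then map-scale
approximations — the same caveat attached to the published map, where the
amount of post-F2 recombination was unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from auanema.io import GenotypeMatrix
from auanema.stats import TestResult, chisq_gof

__all__ = [
    "TwoPointResult",
    "filter_markers",
    "estimate_rf_f2",
    "pairwise_rf",
    "group_markers",
    "kosambi_cm",
    "order_and_space",
    "build_map",
    "distortion_scan",
]

_CODE_TO_INT = {"AA": 0, "AB": 1, "BB": 2, "NA": -1}


@dataclass(frozen=True)
class TwoPointResult:
    marker_i: str
    marker_j: str
    r_hat: float
    lod: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_hat <= 0.5:
            raise ValueError(f"r_hat {self.r_hat} outside [0, 0.5]")
        if self.lod < -1e-9:
            raise ValueError(f"negative lod {self.lod}")


def _encode(gm: GenotypeMatrix) -> np.ndarray:
    out = np.empty(gm.codes.shape, dtype=np.int8)
    for code, val in _CODE_TO_INT.items():
        out[gm.codes == code] = val
    return out


def filter_markers(
    gm: GenotypeMatrix, max_missing: float = 0.5
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop duplicated markers and markers with >= ``max_missing`` missing.

    Duplicates are markers with exactly the same genotype vector across all
    lines; the first (by input order) of each class is kept.  Returns the
    filtered matrix and a removal log with columns (marker_id, reason,
    kept_as).
    """
    log_rows = []
    keep: list[int] = []
    seen: dict[bytes, str] = {}
    n = gm.n_lines
    for j, mid in enumerate(gm.marker_ids):
        col = gm.codes[:, j]
        if (col == "NA").sum() >= max_missing * n:
            log_rows.append((mid, "missing>=50%", ""))
            continue
        key = col.tobytes()
        if key in seen:
            log_rows.append((mid, "duplicate", seen[key]))
            continue
        seen[key] = mid
        keep.append(j)
    log = pd.DataFrame(log_rows, columns=["marker_id", "reason", "kept_as"])
    return gm.select_markers(keep), log


def _joint_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over jointly non-missing lines."""
    ok = (gi >= 0) & (gj >= 0)
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi[ok], gj[ok]), 1.0)
    return counts


def _f2_joint_probs(r: float) -> np.ndarray:
    """Joint genotype probabilities at two loci in an F2 intercross.

    Built from the gamete haplotype frequencies of an F1 in coupling:
    parental haplotypes (1-r)/2 each, recombinants r/2 each; the zygote
    table is the convolution of two independent gametes.  The
    double-heterozygote class is the phase mixture ((1-r)^2 + r^2)/2.
    """
    g = np.array(
        [[(1 - r) / 2, r / 2], [r / 2, (1 - r) / 2]]
    )  # g[a1, a2] haplotype freq
    probs = np.zeros((3, 3))
    for a1 in range(2):
        for a2 in range(2):
            for b1 in range(2):
                for b2 in range(2):
                    probs[a1 + b1, a2 + b2] += g[a1, a2] * g[b1, b2]
    return probs


def _loglik(counts: np.ndarray, r: float) -> float:
    p = _f2_joint_probs(r)
    with np.errstate(divide="ignore"):
        lp = np.log(p)
    lp[p == 0] = -np.inf
    active = counts > 0
    return float((counts[active] * lp[active]).sum())


def estimate_rf_f2(
    gi: Sequence[str] | np.ndarray,
    gj: Sequence[str] | np.ndarray,
    marker_i: str = "m_i",
    marker_j: str = "m_j",
    min_joint: int = 10,
) -> TwoPointResult:
    """Two-point ML recombination fraction and LOD between two F2 markers.

    ``r_hat`` maximizes the intercross likelihood on [0, 0.5] (bounded
    scalar optimization, tolerance 1e-6);
    ``lod = log10 L(r_hat) - log10 L(0.5)``.
    """
    ci = np.array([_CODE_TO_INT[g] for g in gi], dtype=np.int8)
    cj = np.array([_CODE_TO_INT[g] for g in gj], dtype=np.int8)
    counts = _joint_counts(ci, cj)
    if counts.sum() < min_joint:
        raise ValueError(
            f"only {int(counts.sum())} jointly non-missing lines (< {min_joint})"
        )
    res = minimize_scalar(
        lambda r: -_loglik(counts, r),
        bounds=(0.0, 0.5),
        method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat = float(res.x)
    # the bounded optimizer never lands exactly on the boundary; snap when flat
    for edge in (0.0, 0.5):
        if _loglik(counts, edge) >= -res.fun - 1e-12:
            r_hat = edge
            break
    ll_hat = max(_loglik(counts, r_hat), -res.fun)
    lod = (ll_hat - _loglik(counts, 0.5)) / np.log(10)
    return TwoPointResult(marker_i, marker_j, r_hat, max(lod, 0.0))


def pairwise_rf(
    gm: GenotypeMatrix, r_step: float = 0.0025, chunk: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs recombination fraction and LOD via a vectorized grid.

    Evaluates the F2 log-likelihood for every marker pair on an r grid
    ``[0, 0.5]`` with step ``r_step`` and returns (r_hat, lod) matrices.
    Accuracy is limited by the grid, which is ample for LOD-threshold
    grouping; use :func:`estimate_rf_f2` for single pairs at 1e-6.
    """
    enc = _encode(gm)  # lines x markers
    m = gm.n_markers
    onehot = np.zeros((3, m, gm.n_lines))
    for g in range(3):
        onehot[g] = (enc == g).T
    grid = np.arange(0.0, 0.5 + r_step / 2, r_step)
    grid[-1] = 0.5
    logp = np.empty((len(grid), 3, 3))
    for k, r in enumerate(grid):
        p = _f2_joint_probs(r)
        with np.errstate(divide="ignore"):
            logp[k] = np.log(np.maximum(p, 1e-300))
    r_hat = np.zeros((m, m))
    lod = np.zeros((m, m))
    logp_flat = logp.reshape(len(grid), 9).T  # 9 x R
    for s in range(0, m, chunk):
        e = min(s + chunk, m)
        # joint counts for pairs (s:e) x (all): 9 x (e-s) x m
        cnt = np.einsum("gki,hji->ghkj", onehot[:, s:e], onehot).reshape(
            9, e - s, m
        )
        ll = np.tensordot(cnt, logp_flat, axes=(0, 0))  # (e-s) x m x R
        best = ll.argmax(axis=2)
        r_hat[s:e] = grid[best]
        lod[s:e] = (
            np.take_along_axis(ll, best[:, :, None], axis=2)[:, :, 0]
            - ll[:, :, -1]
        ) / np.log(10)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r_hat, 0.0)
    return r_hat, np.maximum(lod, 0.0)


def group_markers(
    results: Iterable[TwoPointResult] | tuple[np.ndarray, np.ndarray],
    marker_ids: Sequence[str] | None = None,
    lod_min: float = 20.0,
    rf_max: float = 0.5,
) -> list[set[str]]:
    """Partition markers into linkage groups.

    An edge joins two markers when ``lod >= lod_min`` and
    ``r_hat <= rf_max``; groups are the connected components.  Accepts
    either an iterable of :class:`TwoPointResult` or the (r_hat, lod)
    matrices from :func:`pairwise_rf` plus ``marker_ids``.  Groups are
    returned largest-first (ties by smallest member id).
    """
    g = nx.Graph()
    if isinstance(results, tuple):
        r_mat, lod_mat = results
        if marker_ids is None:
            raise ValueError("marker_ids required with matrix input")
        g.add_nodes_from(marker_ids)
        ii, jj = np.where(
            np.triu((lod_mat >= lod_min) & (r_mat <= rf_max), k=1)
        )
        g.add_edges_from(
            (marker_ids[i], marker_ids[j]) for i, j in zip(ii, jj)
        )
    else:
        for tp in results:
            g.add_node(tp.marker_i)
            g.add_node(tp.marker_j)
            if tp.lod >= lod_min and tp.r_hat <= rf_max:
                g.add_edge(tp.marker_i, tp.marker_j)
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def kosambi_cm(r: float) -> float:
    """Kosambi map distance in centimorgans: d = 25 ln((1+2r)/(1-2r))."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * float(np.log((1 + 2 * r) / (1 - 2 * r)))


def order_and_space(
    group: Sequence[str],
    gm: GenotypeMatrix,
    r_mat: np.ndarray | None = None,
    lod_mat: np.ndarray | None = None,
) -> pd.DataFrame:
    """Greedy seriation of one linkage group with cumulative Kosambi cM.

    The seed pair is the highest-LOD pair in the group; the chain is then
    extended at either end by the unplaced marker with smallest r to an
    endpoint.  Cumulative positions are Kosambi distances of adjacent
    estimated r values.
    """
    idx = {m: i for i, m in enumerate(gm.marker_ids)}
    members = [m for m in group if m in idx]
    if len(members) == 0:
        raise ValueError("empty group")
    if len(members) == 1:
        return pd.DataFrame({"marker_id": members, "position_cm": [0.0]})
    if r_mat is None or lod_mat is None:
        sub = gm.select_markers([idx[m] for m in members])
        r_mat_s, lod_mat_s = pairwise_rf(sub)
        local = {m: i for i, m in enumerate(members)}
    else:
        sel = [idx[m] for m in members]
        r_mat_s = r_mat[np.ix_(sel, sel)]
        lod_mat_s = lod_mat[np.ix_(sel, sel)]
        local = {m: i for i, m in enumerate(members)}
    k = len(members)
    tri = np.triu(lod_mat_s, 1)
    i0, j0 = np.unravel_index(tri.argmax(), tri.shape)
    chain = [i0, j0]
    unplaced = set(range(k)) - {i0, j0}
    while unplaced:
        left, right = chain[0], chain[-1]
        best = None  # (r, marker, end)
        for u in unplaced:
            for end, anchor in (("L", left), ("R", right)):
                r = r_mat_s[u, anchor]
                if best is None or r < best[0]:
                    best = (r, u, end)
        _, u, end = best
        if end == "L":
            chain.insert(0, u)
        else:
            chain.append(u)
        unplaced.remove(u)
    pos = [0.0]
    for a, b in zip(chain, chain[1:]):
        r = min(float(r_mat_s[a, b]), 0.4999)
        pos.append(pos[-1] + kosambi_cm(r))
    inv = {v: m for m, v in local.items()}
    return pd.DataFrame(
        {"marker_id": [inv[c] for c in chain], "position_cm": pos}
    )


def build_map(
    gm: GenotypeMatrix, lod_min: float = 10.0, rf_max: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, group and order a panel into a genetic map.

    Returns (map table with columns group_id/marker_id/position_cm,
    removal log).
    """
    filtered, log = filter_markers(gm)
    r_mat, lod_mat = pairwise_rf(filtered)
    groups = group_markers((r_mat, lod_mat), filtered.marker_ids, lod_min, rf_max)
    frames = []
    for gi, members in enumerate(groups, 1):
        ordered = order_and_space(sorted(members), filtered, r_mat, lod_mat)
        ordered.insert(0, "group_id", f"G{gi}")
        frames.append(ordered)
    return pd.concat(frames, ignore_index=True), log


def distortion_scan(
    gm: GenotypeMatrix,
    expected_prop: dict[str, tuple[float, float, float]] | None = None,
    default_prop: tuple[float, float, float] = (0.25, 0.5, 0.25),
) -> pd.DataFrame:
    """Per-marker chi-square test against expected genotype proportions.

    ``expected_prop`` maps chromosome -> (p_AA, p_AB, p_BB); chromosomes
    not listed use ``default_prop`` (the F2 intercross 1:2:1).  For panels
    selfed g generations past F2 the appropriate autosomal expectation is
    ((1-h)/2, h, (1-h)/2) with h = 0.5**(g+1).
    """
    expected_prop = expected_prop or {}
    chroms = gm.marker_chromosomes()
    rows = []
    for j, mid in enumerate(gm.marker_ids):
        col = gm.codes[:, j]
        obs = [int((col == g).sum()) for g in ("AA", "AB", "BB")]
        props = expected_prop.get(chroms[j], default_prop)
        if sum(obs) == 0:
            rows.append((mid, chroms[j], np.nan, np.nan))
            continue
        try:
            tr: TestResult = chisq_gof(obs, props)
            rows.append((mid, chroms[j], tr.statistic, tr.p_value))
        except ValueError:
            rows.append((mid, chroms[j], np.inf, 0.0))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "chi2", "p"])
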
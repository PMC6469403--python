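"""Chromosome-level expression comparison: X vs autosomes.

Counts are corrected by library size (total-count scaling to the median
library) and log2-transformed with a pseudocount.  The X:autosome
comparison draws equal random samples of genes from the X and from each
autosome, runs a Kruskal-Wallis test across chromosomes and
Mann-Whitney tests between each autosome-X pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from auanema.io import CountsMatrix
from auanema.stats import TestResult, kruskal_wallis, mann_whitney_u

__all__ = [
    "NormalizedExpression",
    "normalize",
    "xa_test",
    "replicate_consistency",
    "de_threshold_filter",
]


@dataclass(frozen=True)
class NormalizedExpression:
    """log2 library-size-normalized expression (genes x samples)."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    scale: tuple[float, ...]  # per-sample factor applied before log
    gene_chrom: dict[str, str]
    pseudocount: float

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite normalized values")

    def chromosomes(self) -> np.ndarray:
        return np.array([self.gene_chrom[g] for g in self.gene_ids])

    def gene_means(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Mean per-gene expression over the given samples (default all)."""
        if samples is None:
            return self.values.mean(axis=1)
        cols = [self.sample_ids.index(s) for s in samples]
        return self.values[:, cols].mean(axis=1)


def normalize(cm: CountsMatrix, pseudocount: float = 1.0) -> NormalizedExpression:
    """Total-count scaling to the median library size, then log2(x + pc)."""
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = cm.sample_ids[int(np.argmin(totals))]
        raise ValueError(f"sample {bad!r} has zero total count")
    target = float(np.median(totals))
    scale = target / totals
    values = np.log2(cm.counts * scale[None, :] + pseudocount)
    return NormalizedExpression(
        cm.gene_ids,
        cm.sample_ids,
        values,
        tuple(scale),
        dict(cm.gene_chrom),
        pseudocount,
    )


def xa_test(
    ne: NormalizedExpression,
    x_chrom: str,
    n_sample: int = 600,
    seed: int = 0,
    samples: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, TestResult]:
    """X-vs-autosome expression comparison on equal random gene samples.

    Draws ``n_sample`` X genes and ``n_sample`` genes from each autosome
    without replacement (seeded; the size is lowered to the smallest
    chromosome's gene count when necessary), using mean per-gene
    expression over ``samples`` (default: all) as the observation unit.
    Returns (per-autosome Mann-Whitney table, overall Kruskal-Wallis).
    """
    chroms = ne.chromosomes()
    if x_chrom not in set(chroms):
        raise ValueError(f"X chromosome {x_chrom!r} absent from gene_chrom")
    rng = np.random.default_rng(seed)
    means = ne.gene_means(samples)
    autosomes = sorted(c for c in set(chroms) if c != x_chrom)
    sizes = {c: int((chroms == c).sum()) for c in [x_chrom, *autosomes]}
    n_eff = min(n_sample, min(sizes.values()))

    def draw(chrom: str) -> np.ndarray:
        pool = np.where(chroms == chrom)[0]
        picked = rng.choice(pool, size=n_eff, replace=False)
        return means[picked]

    x_vals = draw(x_chrom)
    auto_vals = {c: draw(c) for c in autosomes}
    overall = kruskal_wallis([x_vals, *auto_vals.values()])
    rows = []
    for c in autosomes:
        tr = mann_whitney_u(auto_vals[c], x_vals, mode="auto")
        rows.append((c, x_chrom, n_eff, tr.statistic, tr.p_value, tr.method))
    table = pd.DataFrame(
        rows, columns=["autosome", "x_chrom", "n_genes", "U", "p", "method"]
    )
    return table, overall


def replicate_consistency(
    ne: NormalizedExpression,
    replicate_groups: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis across replicates of each chromosome's expression.

    ``replicate_groups`` maps condition -> sample ids; each chromosome is
    tested within each condition for replicate-to-replicate shifts.
    Returns one row per (condition, chromosome) with a ``flagged`` column
    at p < ``alpha``.
    """
    chroms = ne.chromosomes()
    rows = []
    for condition, samps in replicate_groups.items():
        cols = [ne.sample_ids.index(s) for s in samps]
        if len(cols) < 2:
            raise ValueError(f"condition {condition!r} needs >= 2 replicates")
        for chrom in sorted(set(chroms)):
            sub = ne.values[chroms == chrom][:, cols]
            tr = kruskal_wallis([sub[:, k] for k in range(sub.shape[1])])
            rows.append(
                (condition, chrom, tr.statistic, tr.p_value, tr.p_value < alpha)
            )
    return pd.DataFrame(
        rows, columns=["condition", "chromosome", "H", "p", "flagged"]
    )


def de_threshold_filter(
    stats: pd.DataFrame,
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
    min_abs_lfc: float = 2.0,
    max_padj: float = 0.01,
) -> pd.DataFrame:
    """Plain threshold filter on externally supplied per-gene DE statistics.

    Keeps rows with |log2 fold change| >= ``min_abs_lfc`` and adjusted
    p < ``max_padj``.  The model fitting that produces these statistics is
    outside this package's scope.
    """
    keep = (stats[lfc_col].abs() >= min_abs_lfc) & (stats[padj_col] < max_padj)
    return stats[keep].reset_index(drop=True)
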
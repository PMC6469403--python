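"""Synthetic data generators with planted ground truth.

Every input class the pipeline consumes can be generated here at desk
scale, in place of the deposited sequencing data:

* five-species gene tables and pairwise hit tables whose chromosomes are
  mosaics of seven planted ancestral elements (:func:`gen_species_set`),
* negative-binomial RNA-seq-like count matrices with a planted X
  down-regulation factor (:func:`gen_counts`),
* per-mother progeny count tables with a planted female-ratio shift
  (:func:`gen_progeny`).

All generators are pure functions of (parameters, seed), and each returns
its ground truth alongside the data; downstream recovery tests must consume
only the non-truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from auanema.io import (
    HIT_COLUMNS,
    CountsMatrix,
    GeneTable,
    HitTable,
    ProgenyTable,
)

__all__ = [
    "ElementHistory",
    "fig9_history",
    "gen_species_set",
    "gen_counts",
    "gen_progeny",
]

GENE_SPACING_BP = 10_000
GENE_LENGTH_BP = 5_000


@dataclass(frozen=True)
class ElementHistory:
    """Planted ancestral-element composition of a set of genomes.

    ``species_compositions`` maps species -> chromosome -> ordered list of
    (element, fraction-of-chromosome); fractions sum to 1 per chromosome.
    ``shuffle_intensity`` is the expected number of intra-chromosomal
    segment inversions per chromosome; ``ortholog_dropout`` the per-gene,
    per-species loss probability; ``spurious_hit_rate`` the per-gene rate
    of injected decoy best-hit candidates.
    """

    elements: tuple[str, ...]
    species_compositions: dict[str, dict[str, list[tuple[str, float]]]]
    shuffle_intensity: float = 3.0
    ortholog_dropout: float = 0.1
    spurious_hit_rate: float = 0.02

    def __post_init__(self) -> None:
        used: set[str] = set()
        for sp, chroms in self.species_compositions.items():
            for chrom, comp in chroms.items():
                total = sum(f for _, f in comp)
                if not np.isclose(total, 1.0, atol=1e-9):
                    raise ValueError(
                        f"{sp}/{chrom}: fractions sum to {total}, not 1"
                    )
                for el, _ in comp:
                    if el not in self.elements:
                        raise ValueError(
                            f"{sp}/{chrom}: unknown element {el!r}"
                        )
                    used.add(el)
        unused = set(self.elements) - used
        if unused:
            raise ValueError(f"elements never used: {sorted(unused)}")
        if self.shuffle_intensity < 0:
            raise ValueError("shuffle_intensity must be >= 0")
        for name in ("ortholog_dropout", "spurious_hit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")

    @property
    def species(self) -> list[str]:
        return list(self.species_compositions)


def _eq(els: Sequence[str]) -> list[tuple[str, float]]:
    f = 1.0 / len(els)
    return [(e, f) for e in els]


def fig9_history(
    shuffle_intensity: float = 3.0,
    ortholog_dropout: float = 0.1,
    spurious_hit_rate: float = 0.02,
) -> ElementHistory:
    """The published five-genome Nigon-element mosaic.

    Seven elements NA, NB, NC, ND, NE, NX plus the unplaced NN unit,
    distributed over *P. pacificus* (Ppa), *H. contortus* (Hco),
    *C. elegans* (Cel), *O. tipulae* (Oti) and *A. rhodensis* (Arh).
    Chromosome fractions are split equally among the listed elements
    (the source model does not quantify them).
    """
    comps = {
        "Cel": {
            "I": _eq(["NA"]),
            "II": _eq(["NB"]),
            "III": _eq(["NC"]),
            "IV": _eq(["ND"]),
            "V": _eq(["NE"]),
            "X": _eq(["NX", "NN"]),
        },
        "Hco": {
            "1": _eq(["NA"]),
            "2": _eq(["NB"]),
            "3": _eq(["NC"]),
            "4": _eq(["ND"]),
            "5": _eq(["NE"]),
            "X": _eq(["NX", "NN"]),
        },
        "Ppa": {
            "I": _eq(["NE", "NN"]),
            "II": _eq(["NB"]),
            "III": _eq(["NC"]),
            "IV": _eq(["ND"]),
            "V": _eq(["NA"]),
            "X": _eq(["NX"]),
        },
        "Oti": {
            "I": _eq(["NA"]),
            "II": _eq(["NB"]),
            "III": _eq(["NC"]),
            "IV": _eq(["ND"]),
            "V": _eq(["NN"]),
            "X": _eq(["NX", "NE"]),
        },
        "Arh": {
            "LG1": _eq(["NE"]),
            "LG2": _eq(["NC", "NN"]),
            "LG3": _eq(["NA", "NC"]),
            "LG4": _eq(["NA", "NC", "NN"]),
            "LG5X": _eq(["NX"]),
            "LG6": _eq(["ND"]),
            "LG7": _eq(["NB"]),
        },
    }
    return ElementHistory(
        ("NA", "NB", "NC", "ND", "NE", "NX", "NN"),
        comps,
        shuffle_intensity,
        ortholog_dropout,
        spurious_hit_rate,
    )


def _allocate_element_chunks(
    history: ElementHistory, genes_per_element: int
) -> dict[str, dict[str, list[np.ndarray]]]:
    """Per species: chromosome -> list of ancestral-gene index arrays.

    An element present on k chromosomes of a species is cut into k
    contiguous chunks of its ancestral gene order (mirroring the observed
    sub-element segments of fission products), allocated proportionally to
    the chromosome fractions.
    """
    out: dict[str, dict[str, list[np.ndarray]]] = {}
    for sp, chroms in history.species_compositions.items():
        # element -> list of (chromosome, fraction) in composition order
        demand: dict[str, list[tuple[str, float]]] = {}
        for chrom, comp in chroms.items():
            for el, frac in comp:
                demand.setdefault(el, []).append((chrom, frac))
        chunk_of: dict[tuple[str, str], np.ndarray] = {}
        for el, targets in demand.items():
            weights = np.array([f for _, f in targets])
            shares = weights / weights.sum()
            cuts = np.round(np.cumsum(shares) * genes_per_element).astype(int)
            prev = 0
            for (chrom, _), cut in zip(targets, cuts):
                chunk_of[(el, chrom)] = np.arange(prev, cut)
                prev = cut
        out[sp] = {
            chrom: [chunk_of[(el, chrom)] for el, _ in comp]
            for chrom, comp in chroms.items()
        }
    return out


def _invert_segments(
    order: np.ndarray, intensity: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply Poisson(intensity) random segment inversions to a gene order.

    Each inversion reverses a random contiguous interval spanning 5-30% of
    the chromosome's gene count.
    """
    n = len(order)
    if n < 2 or intensity == 0:
        return order
    order = order.copy()
    for _ in range(rng.poisson(intensity)):
        seg = max(2, int(rng.uniform(0.05, 0.30) * n))
        start = rng.integers(0, n - seg + 1)
        order[start : start + seg] = order[start : start + seg][::-1]
    return order


def gen_species_set(
    history: ElementHistory | None = None,
    genes_per_element: int = 300,
    seed: int = 0,
) -> tuple[dict[str, GeneTable], dict[tuple[str, str], HitTable], pd.DataFrame]:
    """Generate gene tables, pairwise hit tables and the gene->element truth.

    Each element is a pool of ancestral genes; each species lays out its
    chromosomes by concatenating its element chunks, shuffles each
    chromosome with Poisson(shuffle_intensity) segment inversions, and
    drops each gene independently with probability ``ortholog_dropout``.
    Hit tables give the surviving true ortholog a N(500, 50) bitscore and
    inject N(300, 50) decoy hits at ``spurious_hit_rate``; e-values are
    2**(-bitscore) (only ranks matter downstream).

    Returns (gene tables by species, hit tables by ordered species pair,
    truth table with columns species/gene_id/ancestral_id/element).
    """
    history = history or fig9_history()
    if genes_per_element < 20:
        raise ValueError("genes_per_element must be >= 20")
    rng = np.random.default_rng(seed)
    ancestral = {
        el: [f"{el}_{i:04d}" for i in range(genes_per_element)]
        for el in history.elements
    }
    chunks = _allocate_element_chunks(history, genes_per_element)

    gene_tables: dict[str, GeneTable] = {}
    truth_rows = []
    # species -> ancestral_id -> (species gene id, chromosome)
    placed: dict[str, dict[str, str]] = {}
    for sp in history.species:
        records = []
        sp_map: dict[str, str] = {}
        for chrom, comp in history.species_compositions[sp].items():
            anc_ids: list[str] = []
            for (el, _), idx in zip(comp, chunks[sp][chrom]):
                anc_ids.extend(ancestral[el][i] for i in idx)
            kept = [
                a for a in anc_ids if rng.random() >= history.ortholog_dropout
            ]
            order = _invert_segments(
                np.arange(len(kept)), history.shuffle_intensity, rng
            )
            for pos, oi in enumerate(order):
                anc = kept[oi]
                gid = f"{sp}_{anc}"
                start = pos * GENE_SPACING_BP
                records.append(
                    (gid, chrom, start, start + GENE_LENGTH_BP, "+")
                )
                sp_map[anc] = gid
                truth_rows.append((sp, gid, anc, anc.split("_")[0]))
        df = pd.DataFrame(
            records, columns=["gene_id", "chromosome", "start", "end", "strand"]
        ).sort_values(["chromosome", "start"], kind="stable").reset_index(
            drop=True
        )
        gene_tables[sp] = GeneTable(sp, df)
        placed[sp] = sp_map

    hit_tables: dict[tuple[str, str], HitTable] = {}
    species = history.species
    for a in species:
        for b in species:
            if a == b:
                continue
            rows = []
            b_genes = list(placed[b].values())
            for anc, gid_a in placed[a].items():
                gid_b = placed[b].get(anc)
                if gid_b is not None:
                    score = max(50.0, rng.normal(500.0, 50.0))
                    rows.append(_hit_row(gid_a, gid_b, score))
                if rng.random() < history.spurious_hit_rate and b_genes:
                    decoy = b_genes[rng.integers(len(b_genes))]
                    score = max(50.0, rng.normal(300.0, 50.0))
                    rows.append(_hit_row(gid_a, decoy, score))
            df = pd.DataFrame(rows, columns=HIT_COLUMNS)
            hit_tables[(a, b)] = HitTable(df)

    truth = pd.DataFrame(
        truth_rows, columns=["species", "gene_id", "ancestral_id", "element"]
    )
    return gene_tables, hit_tables, truth


def _hit_row(query: str, subject: str, bitscore: float) -> tuple:
    evalue = float(2.0 ** (-min(bitscore, 900.0)))
    return (
        query,
        subject,
        90.0,
        400,
        10,
        1,
        1,
        400,
        1,
        400,
        evalue,
        round(bitscore, 1),
    )


def gen_counts(
    n_genes_per_chrom: Mapping[str, int] | None = None,
    n_samples: int = 4,
    nb_dispersion: float = 0.1,
    library_sizes: Sequence[float] | None = None,
    x_factor: float = 0.3,
    x_chrom: str = "LG5X",
    seed: int = 0,
) -> CountsMatrix:
    """Negative-binomial count matrix with a planted X expression shift.

    Gene mean abundances are log-normal; genes on ``x_chrom`` have their
    means multiplied by ``x_factor`` (< 1 plants an X deficit).  Counts are
    NB(mean, dispersion) per sample, scaled so column sums approximate
    ``library_sizes``.
    """
    if x_factor <= 0:
        raise ValueError("x_factor must be > 0")
    if n_genes_per_chrom is None:
        n_genes_per_chrom = {
            c: 600 for c in ("LG1", "LG2", "LG3", "LG4", "LG5X", "LG6", "LG7")
        }
    if library_sizes is None:
        library_sizes = [5e6] * n_samples
    library_sizes = list(library_sizes)
    if len(library_sizes) != n_samples:
        raise ValueError("library_sizes length must equal n_samples")
    if any(ls <= 0 for ls in library_sizes):
        raise ValueError("library sizes must be positive")
    rng = np.random.default_rng(seed)

    gene_ids: list[str] = []
    chroms: list[str] = []
    for chrom, n in n_genes_per_chrom.items():
        gene_ids.extend(f"{chrom}_g{i:04d}" for i in range(n))
        chroms.extend([chrom] * n)
    n_genes = len(gene_ids)
    base_mean = rng.lognormal(mean=3.0, sigma=1.2, size=n_genes)
    is_x = np.array([c == x_chrom for c in chroms])
    mean = np.where(is_x, base_mean * x_factor, base_mean)
    rel = mean / mean.sum()

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for s in range(n_samples):
        mu = rel * library_sizes[s]
        # NB with gamma-Poisson mixture; nb_dispersion = 1/size
        if nb_dispersion > 0:
            shape = 1.0 / nb_dispersion
            lam = rng.gamma(shape, mu / shape)
        else:
            lam = mu
        counts[:, s] = rng.poisson(lam)

    sample_ids = tuple(f"S{s + 1}" for s in range(n_samples))
    return CountsMatrix(
        tuple(gene_ids),
        sample_ids,
        counts,
        dict(zip(gene_ids, chroms)),
    )


def gen_progeny(
    n_mothers_per_arm: int = 8,
    ratio_control: float = 0.22,
    ratio_rnai: float = 0.43,
    brood_mean: int = 180,
    male_mean: float = 3.0,
    seed: int = 0,
) -> ProgenyTable:
    """Progeny-count table with a planted female-ratio shift.

    Per mother the XX brood size is Poisson(``brood_mean``); the female
    count is Binomial(brood, arm ratio), the rest hermaphrodites; a small
    male count is Poisson(``male_mean``).  Defaults mirror the magnitudes
    of the published RNAi experiment (aggregate female ratios ~0.43 vs
    ~0.22, broods of one to a few hundred).
    """
    for name, r in (("ratio_control", ratio_control), ("ratio_rnai", ratio_rnai)):
        if not 0.0 < r < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    if brood_mean <= 0:
        raise ValueError("brood_mean must be positive")
    if n_mothers_per_arm < 1:
        raise ValueError("n_mothers_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    mother = 0
    for condition, ratio in (("RNAi", ratio_rnai), ("Control", ratio_control)):
        for _ in range(n_mothers_per_arm):
            mother += 1
            brood = max(1, rng.poisson(brood_mean))
            females = rng.binomial(brood, ratio)
            rows.append(
                (
                    f"M{mother:02d}",
                    condition,
                    int(rng.poisson(male_mean)),
                    int(females),
                    int(brood - females),
                )
            )
    return ProgenyTable(
        pd.DataFrame(
            rows,
            columns=["mother_id", "condition", "males", "females", "hermaphrodites"],
        )
    )
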
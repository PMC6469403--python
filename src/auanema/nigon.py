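"""Ancestral linkage-group (Nigon element) inference and chromosome painting.

Rhabditine nematode genomes are mosaics of a small number of deeply
conserved ancestral chromosomal units (Nigon elements, by analogy with the
Muller elements of *Drosophila*).  Two ortholog families that descend from
the same element tend to sit on the same chromosome in every species;
families from different elements co-occur only on fusion chromosomes of
particular lineages.  This module formalizes that signal as a co-linkage
agreement graph over families: an edge joins two families whose shared
species place them on the same chromosome at least an ``alpha`` fraction of
the time (computed only where >= 3 species carry both).  Connected
components of the graph are the inferred elements; per-chromosome sliding
majority votes turn gene-level element labels into painted blocks; fusion
chromosomes are called from the element composition of their assigned
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from auanema.io import GeneTable
from auanema.orthology import OrthologFamilySet

__all__ = [
    "ElementSet",
    "ElementPainting",
    "colinkage_graph",
    "infer_elements",
    "paint",
    "link_table",
]


@dataclass(frozen=True)
class ElementSet:
    """Disjoint sets of ortholog families, one per inferred element.

    ``elements`` maps element_id (E1..Ek, decreasing size) -> list of
    family_ids; families in components smaller than the size floor are in
    ``unassigned``.
    """

    elements: dict[str, list[str]]
    unassigned: list[str]
    agreement_threshold: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fams in self.elements.values():
            overlap = seen & set(fams)
            if overlap:
                raise ValueError(f"family in two elements: {sorted(overlap)[:3]}")
            seen |= set(fams)

    def family_to_element(self) -> dict[str, str]:
        return {
            f: e for e, fams in self.elements.items() for f in fams
        }

    def __len__(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class ElementPainting:
    """Painted chromosome blocks and fusion calls for one species.

    ``blocks`` columns: chromosome, start, end, element, n_genes,
    low_confidence.  ``fusion_calls`` maps chromosome -> set of elements
    holding at least the fusion fraction of its assigned genes.
    """

    species: str
    blocks: pd.DataFrame
    fusion_calls: dict[str, set[str]]


def colinkage_graph(
    families: OrthologFamilySet, alpha: float = 0.7, min_shared_species: int = 3
) -> nx.Graph:
    """Graph over families with edges at co-linkage agreement >= alpha.

    agreement(f, g) = (#species where both present and on the same
    chromosome) / (#species where both present), computed only when the
    denominator is >= ``min_shared_species``.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    sig = families.signatures()
    fam_ids = list(sig.index)
    chrom_codes = np.full(sig.shape, -1, dtype=np.int32)
    for j, sp in enumerate(sig.columns):
        col = sig.iloc[:, j]
        present = col.notna()
        cats = pd.Categorical(col[present])
        chrom_codes[present.to_numpy(), j] = cats.codes
    present = chrom_codes >= 0  # F x S
    n = len(fam_ids)
    shared = np.zeros((n, n), dtype=np.int16)
    agree = np.zeros((n, n), dtype=np.int16)
    for j in range(chrom_codes.shape[1]):
        pj = present[:, j]
        both = np.outer(pj, pj)
        shared += both
        cj = chrom_codes[:, j]
        same = cj[:, None] == cj[None, :]
        agree += both & same
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = agree / shared
    edges = (shared >= min_shared_species) & (ratio >= alpha)
    np.fill_diagonal(edges, False)
    g = nx.Graph()
    g.add_nodes_from(fam_ids)
    ii, jj = np.where(np.triu(edges, 1))
    g.add_edges_from((fam_ids[i], fam_ids[j]) for i, j in zip(ii, jj))
    return g


def infer_elements(
    graph: nx.Graph, min_element_size: int = 20, alpha: float = 0.7
) -> ElementSet:
    """Elements = connected components of the co-linkage graph.

    Components smaller than ``min_element_size`` families go to
    ``unassigned``.  Elements are labeled E1..Ek by decreasing size (ties
    by smallest member id).
    """
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    elements: dict[str, list[str]] = {}
    unassigned: list[str] = []
    k = 0
    for comp in comps:
        if len(comp) >= min_element_size:
            k += 1
            elements[f"E{k}"] = comp
        else:
            unassigned.extend(comp)
    return ElementSet(elements, sorted(unassigned), alpha)


def _species_gene_elements(
    families: OrthologFamilySet,
    elements: ElementSet,
    gene_table: GeneTable,
    species: str,
) -> pd.DataFrame:
    """Element-labeled genes of one species, ordered by (chromosome, start)."""
    fam2el = elements.family_to_element()
    members = families.families
    mine = members[members["species"] == species]
    labeled = mine.assign(element=mine["family_id"].map(fam2el)).dropna(
        subset=["element"]
    )
    coords = gene_table.records[["gene_id", "chromosome", "start", "end"]]
    merged = labeled.merge(coords, on="gene_id", suffixes=("_fam", ""))
    return merged.sort_values(["chromosome", "start"], kind="stable")


def paint(
    families: OrthologFamilySet,
    elements: ElementSet,
    gene_tables: Mapping[str, GeneTable],
    species: str,
    window_genes: int = 10,
    min_fusion_fraction: float = 0.1,
) -> ElementPainting:
    """Paint one species' chromosomes into element blocks and call fusions.

    Element-assigned genes are ordered by position per chromosome; a
    sliding majority vote over ``window_genes`` consecutive assigned genes
    smooths the labels; runs of a single label become blocks spanning the
    first to last gene coordinate.  ``fusion_calls`` lists every element
    holding >= ``min_fusion_fraction`` of a chromosome's assigned genes.
    Chromosomes with fewer assigned genes than the window get one
    simple-majority block flagged low-confidence.
    """
    if window_genes < 3:
        raise ValueError("window_genes must be >= 3")
    if not 0.0 < min_fusion_fraction < 1.0:
        raise ValueError("min_fusion_fraction must be in (0, 1)")
    genes = _species_gene_elements(
        families, elements, gene_tables[species], species
    )
    block_rows = []
    fusion: dict[str, set[str]] = {}
    for chrom, sub in genes.groupby("chromosome", sort=True):
        labels = sub["element"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        n = len(labels)
        counts = pd.Series(labels).value_counts()
        fusion[chrom] = {
            el for el, c in counts.items() if c / n >= min_fusion_fraction
        }
        if n < window_genes:
            major = counts.index[0]
            block_rows.append(
                (chrom, int(starts.min()), int(ends.max()), major, n, True)
            )
            continue
        half = window_genes // 2
        smoothed = np.empty(n, dtype=object)
        for i in range(n):
            lo = max(0, min(i - half, n - window_genes))
            window = labels[lo : lo + window_genes]
            vc = pd.Series(window).value_counts()
            top = vc.max()
            # deterministic tie-break: keep the gene's own label if tied,
            # else the lexicographically smallest winner
            winners = sorted(vc.index[vc == top])
            smoothed[i] = labels[i] if labels[i] in winners else winners[0]
        run_start = 0
        for i in range(1, n + 1):
            if i == n or smoothed[i] != smoothed[run_start]:
                block_rows.append(
                    (
                        chrom,
                        int(starts[run_start]),
                        int(ends[i - 1]),
                        smoothed[run_start],
                        i - run_start,
                        False,
                    )
                )
                run_start = i
    blocks = pd.DataFrame(
        block_rows,
        columns=[
            "chromosome",
            "start",
            "end",
            "element",
            "n_genes",
            "low_confidence",
        ],
    )
    return ElementPainting(species, blocks, fusion)


def link_table(
    families: OrthologFamilySet,
    gene_tables: Mapping[str, GeneTable],
    species_a: str,
    species_b: str,
) -> pd.DataFrame:
    """Per-family link endpoints between two species (Circos-style input).

    One row per family with members in both species, giving each member's
    chromosome and interval midpoint.
    """
    sig = families.families
    for sp in (species_a, species_b):
        if sp not in set(sig["species"]):
            raise ValueError(f"species {sp!r} absent from families")

    def mids(sp: str) -> pd.DataFrame:
        rec = gene_tables[sp].records
        mid = ((rec["start"] + rec["end"]) // 2).astype(int)
        coords = pd.DataFrame(
            {
                "gene_id": rec["gene_id"],
                "chromosome": rec["chromosome"],
                "midpoint": mid,
            }
        )
        mine = sig[sig["species"] == sp][["family_id", "gene_id"]]
        return mine.merge(coords, on="gene_id")

    a = mids(species_a).rename(
        columns={"chromosome": "chrom_a", "midpoint": "midpoint_a"}
    )
    b = mids(species_b).rename(
        columns={"chromosome": "chrom_b", "midpoint": "midpoint_b"}
    )
    out = a.merge(b, on="family_id")[
        ["family_id", "chrom_a", "midpoint_a", "chrom_b", "midpoint_b"]
    ]
    return out.sort_values(["chrom_a", "midpoint_a"], kind="stable").reset_index(
        drop=True
    )
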
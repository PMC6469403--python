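"""Reciprocal-best-hit orthology and multi-species family assembly.

Orthologs between species pairs are called as reciprocal best hits (RBH) in
score tables of the BLAST outfmt-6 dialect, after discarding hits with
e-value above 0.01.  Pairwise RBH sets across >= 3 species are pooled into
ortholog families as connected components of the union graph, with a
deterministic weakest-edge repair for components that would place two genes
of one species in the same family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

from auanema.io import GeneTable, HitTable

__all__ = [
    "OrthologPairs",
    "OrthologFamilySet",
    "best_hits",
    "rbh",
    "build_families",
]

EVALUE_CUTOFF = 0.01


@dataclass(frozen=True)
class OrthologPairs:
    """RBH ortholog pairs for one ordered species pair."""

    species_a: str
    species_b: str
    pairs: pd.DataFrame  # gene_a, gene_b, bitscore_ab, bitscore_ba

    def __post_init__(self) -> None:
        required = ["gene_a", "gene_b", "bitscore_ab", "bitscore_ba"]
        if list(self.pairs.columns) != required:
            raise ValueError(f"pairs columns must be {required}")
        for col in ("gene_a", "gene_b"):
            if self.pairs[col].duplicated().any():
                raise ValueError(f"gene appears twice in column {col}")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class OrthologFamilySet:
    """Cross-species ortholog families with chromosome signatures.

    ``families`` columns: family_id, species, gene_id, chromosome — one row
    per member; at most one member per species per family.
    """

    families: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["family_id", "species", "gene_id", "chromosome"]
        if list(self.families.columns) != required:
            raise ValueError(f"families columns must be {required}")
        if self.families.duplicated(["family_id", "species"]).any():
            raise ValueError("family with two members from one species")

    @property
    def family_ids(self) -> list[str]:
        return list(self.families["family_id"].unique())

    def signatures(self) -> pd.DataFrame:
        """Wide table family_id x species of chromosome labels (NaN absent)."""
        return self.families.pivot(
            index="family_id", columns="species", values="chromosome"
        )

    def members(self) -> pd.DataFrame:
        return self.families


def best_hits(hits: HitTable, evalue_cutoff: float = EVALUE_CUTOFF) -> dict[str, str]:
    """Best subject per query: max bitscore, ties to lower e-value then
    lexicographically smaller subject id; hits above the e-value cutoff are
    discarded first."""
    df = hits.rows
    df = df[df["evalue"] <= evalue_cutoff]
    if df.empty:
        return {}
    ranked = df.sort_values(
        ["query_id", "bitscore", "evalue", "subject_id"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    top = ranked.drop_duplicates("query_id", keep="first")
    return dict(zip(top["query_id"], top["subject_id"]))


def rbh(
    hits_ab: HitTable,
    hits_ba: HitTable,
    species_a: str = "A",
    species_b: str = "B",
    evalue_cutoff: float = EVALUE_CUTOFF,
) -> OrthologPairs:
    """Reciprocal best hits: (a, b) kept iff a's best is b and b's best is a."""
    fwd = best_hits(hits_ab, evalue_cutoff)
    rev = best_hits(hits_ba, evalue_cutoff)
    score_ab = _best_scores(hits_ab, evalue_cutoff)
    score_ba = _best_scores(hits_ba, evalue_cutoff)
    rows = [
        (a, b, score_ab[(a, b)], score_ba[(b, a)])
        for a, b in fwd.items()
        if rev.get(b) == a
    ]
    rows.sort()
    return OrthologPairs(
        species_a,
        species_b,
        pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "bitscore_ab", "bitscore_ba"]
        )
        if rows
        else pd.DataFrame(
            columns=["gene_a", "gene_b", "bitscore_ab", "bitscore_ba"]
        ),
    )


def _best_scores(
    hits: HitTable, evalue_cutoff: float
) -> dict[tuple[str, str], float]:
    df = hits.rows
    df = df[df["evalue"] <= evalue_cutoff]
    if df.empty:
        return {}
    grouped = df.groupby(["query_id", "subject_id"])["bitscore"].max()
    return grouped.to_dict()


def build_families(
    pairs: list[OrthologPairs],
    gene_tables: Mapping[str, GeneTable],
    min_species: int = 3,
) -> OrthologFamilySet:
    """Pool pairwise RBH sets into multi-species ortholog families.

    Families are connected components of the union RBH graph over
    (species, gene) nodes.  A component holding two genes of one species is
    repaired by iteratively removing its lowest-weight edge (weight =
    min(bitscore_ab, bitscore_ba)) until every species is represented at
    most once in each piece.  Families spanning fewer than ``min_species``
    species are dropped.  Chromosome signatures come from the gene tables.
    """
    gene_chrom: dict[tuple[str, str], str] = {}
    for sp, gt in gene_tables.items():
        for g, c in gt.gene_chromosome().items():
            gene_chrom[(sp, g)] = c

    g = nx.Graph()
    for op in pairs:
        for row in op.pairs.itertuples(index=False):
            u = (op.species_a, row.gene_a)
            v = (op.species_b, row.gene_b)
            for node in (u, v):
                if node not in gene_chrom:
                    raise ValueError(
                        f"gene {node[1]!r} of species {node[0]!r} "
                        "absent from gene tables"
                    )
            w = min(float(row.bitscore_ab), float(row.bitscore_ba))
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)

    components = [set(c) for c in nx.connected_components(g)]
    consistent: list[set] = []
    while components:
        comp = components.pop()
        species = [sp for sp, _ in comp]
        if len(species) == len(set(species)):
            consistent.append(comp)
            continue
        sub = g.subgraph(comp)
        weakest = min(sub.edges(data="weight"), key=lambda e: (e[2], e[:2]))
        g.remove_edge(weakest[0], weakest[1])
        sub2 = g.subgraph(comp)
        components.extend(set(c) for c in nx.connected_components(sub2))

    consistent = [c for c in consistent if len(c) >= min_species]
    # deterministic family ids: sort components by their smallest member
    consistent.sort(key=lambda c: sorted(c)[0])
    rows = []
    for i, comp in enumerate(consistent, 1):
        fid = f"F{i:05d}"
        for sp, gene in sorted(comp):
            rows.append((fid, sp, gene, gene_chrom[(sp, gene)]))
    return OrthologFamilySet(
        pd.DataFrame(
            rows, columns=["family_id", "species", "gene_id", "chromosome"]
        )
    )
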
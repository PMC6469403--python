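"""Element inference, chromosome painting and link tables."""

import numpy as np
import pandas as pd
import pytest

from auanema.io import GeneTable
from auanema.nigon import (
    ElementSet,
    colinkage_graph,
    infer_elements,
    link_table,
    paint,
)
from auanema.orthology import OrthologFamilySet


def family_set(rows):
    """rows: (family_id, species, gene_id, chromosome)"""
    return OrthologFamilySet(
        pd.DataFrame(rows, columns=["family_id", "species", "gene_id", "chromosome"])
    )


def true_element_of_families(families, truth):
    """Majority planted element per family."""
    tmap = dict(zip(truth.gene_id, truth.element))
    mem = families.families.assign(true_el=families.families.gene_id.map(tmap))
    return mem.groupby("family_id").true_el.agg(lambda s: s.mode()[0])


class TestColinkageGraph:
    def test_same_chromosome_everywhere_gives_edge(self):
        rows = []
        for f in ("F1", "F2"):
            for sp in ("s1", "s2", "s3", "s4", "s5"):
                rows.append((f, sp, f"{sp}_{f}", "chrA"))
        g = colinkage_graph(family_set(rows), alpha=0.7)
        assert g.has_edge("F1", "F2")

    def test_single_shared_chromosome_no_edge(self):
        # same chromosome only in 1 of 5 species: agreement 0.2 < alpha
        rows = []
        for sp in ("s1", "s2", "s3", "s4", "s5"):
            rows.append(("F1", sp, f"{sp}_F1", "chrA"))
            rows.append(("F2", sp, f"{sp}_F2", "chrA" if sp == "s5" else "chrB"))
        g = colinkage_graph(family_set(rows), alpha=0.6)
        assert not g.has_edge("F1", "F2")

    def test_matches_brute_force_agreement(self):
        rng = np.random.default_rng(5)
        species = [f"s{i}" for i in range(5)]
        rows = []
        for f in range(12):
            present = rng.random(5) > 0.2
            if present.sum() < 3:
                present[:3] = True
            for sp, pres in zip(species, present):
                if pres:
                    rows.append(
                        (f"F{f:02d}", sp, f"{sp}_F{f}", f"chr{rng.integers(3)}")
                    )
        fams = family_set(rows)
        alpha = 0.6
        g = colinkage_graph(fams, alpha=alpha)
        sig = fams.signatures()
        for i, fi in enumerate(sig.index):
            for fj in sig.index[i + 1 :]:
                a, b = sig.loc[fi], sig.loc[fj]
                both = a.notna() & b.notna()
                expected = False
                if both.sum() >= 3:
                    agree = (a[both] == b[both]).mean()
                    expected = agree >= alpha
                assert g.has_edge(fi, fj) == expected

    def test_alpha_zero_rejected_but_tiny_alpha_connects(self):
        rows = []
        for f in ("F1", "F2"):
            for sp in ("s1", "s2", "s3"):
                # same chromosome only in s1: agreement 1/3
                chrom = "chrA" if (f == "F1" or sp == "s1") else "chrB"
                rows.append((f, sp, f"{sp}_{f}", chrom))
        with pytest.raises(ValueError):
            colinkage_graph(family_set(rows), alpha=0.0)
        g = colinkage_graph(family_set(rows), alpha=1e-9)
        assert g.has_edge("F1", "F2")  # threshold limit: single component

    def test_two_species_families_produce_no_edges(self):
        rows = []
        for f in ("F1", "F2", "F3"):
            for sp in ("s1", "s2"):
                rows.append((f, sp, f"{sp}_{f}", "chrA"))
        g = colinkage_graph(family_set(rows), alpha=0.5)
        assert g.number_of_edges() == 0
        els = infer_elements(g, min_element_size=1)
        assert all(len(f) == 1 for f in els.elements.values())


class TestInferElements:
    def test_seven_elements_recovered(self, fig9_families, fig9_dataset):
        _, _, truth = fig9_dataset
        g = colinkage_graph(fig9_families)
        els = infer_elements(g)
        assert len(els) == 7
        fam_true = true_element_of_families(fig9_families, truth)
        fam2el = els.family_to_element()
        common = [f for f in fam_true.index if f in fam2el]
        # adjusted Rand index against the planted partition
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(
            [fam_true[f] for f in common], [fam2el[f] for f in common]
        )
        assert ari >= 0.95

    def test_small_components_set_aside(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([(f"A{i}", f"A{i+1}") for i in range(25)])
        g.add_edge("B1", "B2")
        els = infer_elements(g, min_element_size=20)
        assert len(els) == 1
        assert set(els.unassigned) == {"B1", "B2"}

    def test_labels_ordered_by_size(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from([(f"A{i}", f"A{i+1}") for i in range(30)])
        g.add_edges_from([(f"B{i}", f"B{i+1}") for i in range(40)])
        els = infer_elements(g, min_element_size=5)
        assert len(els.elements["E1"]) > len(els.elements["E2"])


class TestPaint:
    def test_fusion_calls_match_planted_mosaic(self, fig9_families, fig9_dataset):
        genes, _, truth = fig9_dataset
        g = colinkage_graph(fig9_families)
        els = infer_elements(g)
        painting = paint(fig9_families, els, genes, "Arh")
        fam_true = true_element_of_families(fig9_families, truth)
        el_name = {
            el: fam_true.reindex(fids).dropna().mode()[0]
            for el, fids in els.elements.items()
        }
        calls = {
            c: {el_name[e] for e in s} for c, s in painting.fusion_calls.items()
        }
        assert calls["LG2"] == {"NC", "NN"}
        assert calls["LG3"] == {"NA", "NC"}
        assert calls["LG4"] == {"NA", "NC", "NN"}
        for single, el in (
            ("LG1", "NE"),
            ("LG5X", "NX"),
            ("LG6", "ND"),
            ("LG7", "NB"),
        ):
            assert calls[single] == {el}

    def test_single_element_chromosome_one_block(self):
        rows = []
        genes = []
        for i in range(30):
            rows.append((f"F{i:02d}", "sp", f"g{i}", "chr1"))
            for other in ("s2", "s3"):
                rows.append((f"F{i:02d}", other, f"{other}_g{i}", "c"))
            genes.append((f"g{i}", "chr1", i * 100, i * 100 + 50, "+"))
        fams = family_set(rows)
        gt = GeneTable(
            "sp",
            pd.DataFrame(
                genes, columns=["gene_id", "chromosome", "start", "end", "strand"]
            ),
        )
        els = ElementSet({"E1": [f"F{i:02d}" for i in range(30)]}, [], 0.7)
        painting = paint(fams, els, {"sp": gt}, "sp")
        assert len(painting.blocks) == 1
        assert painting.fusion_calls["chr1"] == {"E1"}

    def test_wider_window_fewer_blocks(self):
        rows = []
        genes = []
        rng = np.random.default_rng(0)
        labels = ["E1" if (i // 3) % 2 == 0 else "E2" for i in range(60)]
        for i, lab in enumerate(labels):
            rows.append((f"F{i:02d}", "sp", f"g{i}", "chr1"))
            for other in ("s2", "s3"):
                rows.append((f"F{i:02d}", other, f"{other}_g{i}", "c"))
            genes.append((f"g{i}", "chr1", i * 100, i * 100 + 50, "+"))
        fams = family_set(rows)
        gt = GeneTable(
            "sp",
            pd.DataFrame(
                genes, columns=["gene_id", "chromosome", "start", "end", "strand"]
            ),
        )
        els = ElementSet(
            {
                "E1": [f"F{i:02d}" for i, l in enumerate(labels) if l == "E1"],
                "E2": [f"F{i:02d}" for i, l in enumerate(labels) if l == "E2"],
            },
            [],
            0.7,
        )
        blocks_small = paint(fams, els, {"sp": gt}, "sp", window_genes=3).blocks
        blocks_large = paint(fams, els, {"sp": gt}, "sp", window_genes=11).blocks
        assert len(blocks_large) < len(blocks_small)

    def test_fusion_fraction_monotone(self, fig9_families, fig9_dataset):
        genes, _, _ = fig9_dataset
        g = colinkage_graph(fig9_families)
        els = infer_elements(g)
        lo = paint(fig9_families, els, genes, "Arh", min_fusion_fraction=0.05)
        hi = paint(fig9_families, els, genes, "Arh", min_fusion_fraction=0.3)
        for chrom in lo.fusion_calls:
            assert hi.fusion_calls[chrom] <= lo.fusion_calls[chrom]


class TestLinkTable:
    def test_x_links_land_on_partner_x(self, clean_dataset):
        import itertools

        from auanema.orthology import build_families, rbh

        genes, all_hits, _ = clean_dataset
        species = sorted(genes)
        pairs = [
            rbh(all_hits[(a, b)], all_hits[(b, a)], a, b)
            for a, b in itertools.combinations(species, 2)
        ]
        fams = build_families(pairs, genes)
        links = link_table(fams, genes, "Arh", "Cel")
        x_links = links[links.chrom_a == "LG5X"]
        assert len(x_links) > 0
        assert (x_links.chrom_b == "X").all()

    def test_proportions_sum_to_one(self, fig9_families, fig9_dataset):
        genes, _, _ = fig9_dataset
        links = link_table(fig9_families, genes, "Arh", "Cel")
        for chrom, sub in links.groupby("chrom_a"):
            props = sub.chrom_b.value_counts(normalize=True)
            assert props.sum() == pytest.approx(1.0)

    def test_missing_species_rejected(self, fig9_families, fig9_dataset):
        genes, _, _ = fig9_dataset
        with pytest.raises(ValueError, match="absent"):
            link_table(fig9_families, genes, "Arh", "Xenopus")
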
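"""Marker filtering, two-point RF/LOD, grouping, Kosambi, distortion."""

import numpy as np
import pytest

from auanema.inheritance import default_marker_map, simulate_f2_panel
from auanema.io import GenotypeMatrix
from auanema.linkage import (
    TwoPointResult,
    build_map,
    distortion_scan,
    estimate_rf_f2,
    filter_markers,
    group_markers,
    kosambi_cm,
    order_and_space,
    pairwise_rf,
)


def matrix_from_codes(codes, chrom="c1"):
    codes = np.asarray(codes, dtype="<U2")
    n_lines, n_markers = codes.shape
    marker_ids = tuple(f"m{j}" for j in range(n_markers))
    return GenotypeMatrix(
        tuple(f"L{i}" for i in range(n_lines)),
        marker_ids,
        codes,
        {m: (chrom, float(j)) for j, m in enumerate(marker_ids)},
    )


def simulate_two_markers(r, n, seed):
    """Directly simulate F2 genotypes at two loci with recombination r."""
    rng = np.random.default_rng(seed)
    haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    probs = [(1 - r) / 2, r / 2, r / 2, (1 - r) / 2]
    g1 = haps[rng.choice(4, size=n, p=probs)]
    g2 = haps[rng.choice(4, size=n, p=probs)]
    geno = g1 + g2  # 0/1/2 per locus
    code = np.array(["AA", "AB", "BB"])
    return code[geno[:, 0]], code[geno[:, 1]]


class TestFilter:
    def test_duplicates_collapsed_keep_first(self):
        codes = [["AA", "AA", "AB"], ["AB", "AB", "AA"], ["BB", "BB", "AA"]]
        gm = matrix_from_codes(codes)
        filtered, log = filter_markers(gm)
        assert filtered.marker_ids == ("m0", "m2")
        assert list(log.reason) == ["duplicate"]
        assert list(log.kept_as) == ["m0"]

    def test_missing_boundary_is_50pct_inclusive(self):
        # 95 lines: 48 missing (50.5%) removed, 47 (49.5%) kept
        rng = np.random.default_rng(0)
        base = rng.choice(["AA", "AB", "BB"], size=(95, 2)).astype("<U2")
        base[:48, 0] = "NA"
        base[:47, 1] = "NA"
        gm = matrix_from_codes(base)
        filtered, log = filter_markers(gm)
        assert "m0" not in filtered.marker_ids
        assert "m1" in filtered.marker_ids

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        codes = rng.choice(["AA", "AB", "BB", "NA"], size=(20, 30))
        gm = matrix_from_codes(codes)
        filtered, _ = filter_markers(gm)
        # brute force
        survivors = []
        seen = set()
        for j in range(30):
            col = tuple(codes[:, j])
            if sum(c == "NA" for c in col) >= 10:
                continue
            if col in seen:
                continue
            seen.add(col)
            survivors.append(f"m{j}")
        assert list(filtered.marker_ids) == survivors


class TestEstimateRf:
    def test_perfect_linkage(self):
        g = np.array(["AA"] * 10 + ["AB"] * 20 + ["BB"] * 10)
        res = estimate_rf_f2(g, g)
        assert res.r_hat == pytest.approx(0.0, abs=1e-4)
        assert res.lod > 10

    def test_independent_markers_near_half(self):
        rejections = 0
        for seed in range(20):
            gi, _ = simulate_two_markers(0.5, 95, seed)
            _, gj = simulate_two_markers(0.5, 95, seed + 1000)
            res = estimate_rf_f2(gi, gj)
            if res.lod >= 1:
                rejections += 1
        assert rejections <= 3  # lod < 1 in >= 85% of null seeds

    def test_recovery_at_10cm(self):
        r_true = 0.5 * (1 - np.exp(-2 * 0.10))  # Haldane r at 10 cM
        gi, gj = simulate_two_markers(r_true, 500, seed=7)
        res = estimate_rf_f2(gi, gj)
        assert res.r_hat == pytest.approx(r_true, abs=0.02)

    def test_optimum_beats_grid(self):
        gi, gj = simulate_two_markers(0.2, 200, seed=3)
        res = estimate_rf_f2(gi, gj)
        from auanema.linkage import _joint_counts, _loglik, _CODE_TO_INT

        ci = np.array([_CODE_TO_INT[g] for g in gi])
        cj = np.array([_CODE_TO_INT[g] for g in gj])
        counts = _joint_counts(ci, cj)
        ll_hat = _loglik(counts, res.r_hat)
        for r in np.arange(0.0, 0.5001, 0.001):
            assert ll_hat >= _loglik(counts, min(r, 0.5)) - 1e-6

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            estimate_rf_f2(["AA"] * 5 + ["NA"] * 5, ["NA"] * 5 + ["AA"] * 5)


class TestGrouping:
    def test_matrix_grouping_matches_pair_objects(self):
        rng = np.random.default_rng(2)
        codes = rng.choice(["AA", "AB", "BB"], size=(50, 6))
        gm = matrix_from_codes(codes)
        r, lod = pairwise_rf(gm)
        by_matrix = group_markers((r, lod), gm.marker_ids, lod_min=3)
        results = []
        for i in range(6):
            for j in range(i + 1, 6):
                results.append(
                    TwoPointResult(f"m{i}", f"m{j}", float(r[i, j]), float(lod[i, j]))
                )
        by_objects = group_markers(results, lod_min=3)
        assert by_matrix == by_objects

    def test_infinite_threshold_gives_singletons(self):
        rng = np.random.default_rng(3)
        codes = rng.choice(["AA", "AB", "BB"], size=(30, 5))
        gm = matrix_from_codes(codes)
        r, lod = pairwise_rf(gm)
        groups = group_markers((r, lod), gm.marker_ids, lod_min=np.inf)
        assert len(groups) == 5

    def test_invariant_to_marker_order(self):
        gm = simulate_f2_panel(
            default_marker_map(markers_per_autosome=10, x_markers=5),
            n_lines=60,
            expansion_generations=(0, 0),
            seed=5,
        )
        r, lod = pairwise_rf(gm)
        groups = group_markers((r, lod), gm.marker_ids, lod_min=6)
        perm = np.random.default_rng(0).permutation(gm.n_markers)
        gm2 = gm.select_markers(perm)
        r2, lod2 = pairwise_rf(gm2)
        groups2 = group_markers((r2, lod2), gm2.marker_ids, lod_min=6)
        assert sorted(map(sorted, groups)) == sorted(map(sorted, groups2))


class TestKosambi:
    def test_anchor_values(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.25) == pytest.approx(25 * np.log(3), abs=1e-9)

    def test_small_r_linear_limit(self):
        r = 0.01
        assert kosambi_cm(r) == pytest.approx(100 * r, rel=0.01)

    def test_strictly_increasing_and_above_100r(self):
        rs = np.linspace(0.0, 0.49, 50)
        ds = [kosambi_cm(r) for r in rs]
        assert all(b > a for a, b in zip(ds, ds[1:]))
        assert all(d >= 100 * r for r, d in zip(rs, ds))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kosambi_cm(0.5)


class TestOrdering:
    def test_recovers_planted_order(self):
        gm = simulate_f2_panel(
            default_marker_map(n_autosomes=1, markers_per_autosome=12, x_markers=3),
            n_lines=500,
            expansion_generations=(0, 0),
            p_female_generation=0.0,
            seed=6,
        )
        chroms = gm.marker_chromosomes()
        members = [m for m, c in zip(gm.marker_ids, chroms) if c == "LG1"]
        ordered = order_and_space(members, gm)
        got = list(ordered.marker_id)
        assert got == members or got == members[::-1]
        assert (ordered.position_cm.diff().dropna() >= 0).all()

    def test_single_marker_group(self):
        gm = matrix_from_codes([["AA"], ["AB"], ["BB"]])
        ordered = order_and_space(["m0"], gm)
        assert list(ordered.position_cm) == [0.0]


class TestDistortion:
    def test_null_calibration(self):
        rng = np.random.default_rng(8)
        n_lines, n_markers = 200, 300
        geno = rng.choice(["AA", "AB", "BB"], size=(n_lines, n_markers),
                          p=[0.25, 0.5, 0.25])
        gm = matrix_from_codes(geno)
        scan = distortion_scan(gm)
        frac = (scan.p < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.035)

    def test_planted_distortion_flagged(self):
        rng = np.random.default_rng(9)
        normal = rng.choice(["AA", "AB", "BB"], size=(95, 5), p=[0.25, 0.5, 0.25])
        distorted = rng.choice(["AA", "AB", "BB"], size=(95, 2), p=[0.03, 0.07, 0.9])
        gm = matrix_from_codes(np.hstack([normal, distorted]))
        scan = distortion_scan(gm)
        assert (scan.p[5:] < 1e-6).all()
        assert (scan.p[:5] > 1e-4).all()

    def test_all_het_x_extreme(self):
        gm = matrix_from_codes(np.full((95, 3), "AB"), chrom="LG5X")
        scan = distortion_scan(gm)
        assert (scan.p < 1e-10).all()


def test_build_map_end_to_end_small():
    gm = simulate_f2_panel(
        default_marker_map(n_autosomes=2, markers_per_autosome=15, x_markers=8),
        n_lines=80,
        expansion_generations=(0, 0),
        seed=10,
        missing_rate=0.02,
    )
    table, log = build_map(gm, lod_min=8)
    assert table.group_id.nunique() == 3
    # groups correspond to planted chromosomes
    table["chrom"] = table.marker_id.str.split("_").str[0]
    for _, sub in table.groupby("group_id"):
        assert sub.chrom.nunique() == 1
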
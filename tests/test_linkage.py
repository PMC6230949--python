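import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kendalltau

from radmap import linkage, sim
from radmap.linkage import (
    MISSING,
    build_map,
    construct_map,
    group_markers,
    haldane_cm,
    haldane_r,
    mask_isolated_flips,
    order_markers,
    pairwise_all,
    pairwise_linkage,
)
from conftest import make_calls


def brute_force_lod(n: int, R: int) -> float:
    """Independent oracle: log10 likelihood ratio at the clamped ML estimate."""
    r_hat = min(max(R / n, 1 / (2 * n)), 0.5)
    log_lr = 0.0
    for _ in range(R):
        log_lr += math.log10(r_hat / 0.5)
    for _ in range(n - R):
        log_lr += math.log10((1 - r_hat) / 0.5)
    return log_lr


class TestHaldane:
    def test_zero(self):
        assert haldane_cm(0.0) == 0.0

    def test_quarter(self):
        assert haldane_cm(0.25) == pytest.approx(-50 * math.log(0.5), abs=1e-9)
        assert haldane_cm(0.25) == pytest.approx(34.657, abs=1e-3)

    def test_out_of_range(self):
        for r in (0.5, 0.7, -0.01):
            with pytest.raises(ValueError):
                haldane_cm(r)

    def test_asymptote(self):
        assert haldane_r(1e9) == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(0.0, 0.4999, allow_nan=False))
    def test_round_trip(self, r):
        assert haldane_r(haldane_cm(r)) == pytest.approx(r, abs=1e-12)

    @given(st.floats(0.0, 400.0))
    def test_inverse_round_trip(self, d):
        assert haldane_cm(haldane_r(d)) == pytest.approx(d, abs=1e-9, rel=1e-9)


class TestPairwise:
    def test_known_example_n50_r5(self):
        # 50 co-called individuals, 5 mismatches
        a = "0" * 50
        b = "1" * 5 + "0" * 45
        calls = make_calls([a, b])
        pl = pairwise_linkage(calls, 0, 1)
        assert pl.n == 50 and pl.mismatches == 5
        assert pl.rf == pytest.approx(0.1)
        assert pl.phase == "coupling"
        assert pl.lod == pytest.approx(7.992, abs=1e-3)
        assert pl.lod == pytest.approx(brute_force_lod(50, 5), abs=1e-9)

    def test_identical_columns_clamped(self):
        calls = make_calls(["01" * 25, "01" * 25])
        pl = pairwise_linkage(calls, 0, 1)
        assert pl.rf == pytest.approx(0.01)  # 1/(2*50)
        assert pl.phase == "coupling"
        assert pl.lod == pytest.approx(50 * math.log10(2 * 0.99), abs=1e-9)

    def test_null(self):
        calls = make_calls(["0" * 50, "1" * 25 + "0" * 25])
        pl = pairwise_linkage(calls, 0, 1)
        assert pl.rf == 0.5
        assert pl.lod == pytest.approx(0.0, abs=1e-12)

    def test_repulsion_phase(self):
        calls = make_calls(["0" * 20, "1" * 18 + "0" * 2])
        pl = pairwise_linkage(calls, 0, 1)
        assert pl.phase == "repulsion"
        assert pl.rf == pytest.approx(2 / 20)

    def test_no_overlap_undefined(self):
        calls = make_calls(["00--", "--11"])
        pl = pairwise_linkage(calls, 0, 1)
        assert not pl.defined

    def test_matrix_agrees_with_single_pairs(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 2, (6, 40)).astype(np.int8)
        calls[rng.random((6, 40)) < 0.2] = MISSING
        table = pairwise_all(calls)
        for i in range(6):
            for j in range(i + 1, 6):
                single = pairwise_linkage(calls, i, j)
                multi = table.pair(i, j)
                assert single.n == multi.n and single.mismatches == multi.mismatches
                if single.defined:
                    assert single.rf == pytest.approx(multi.rf)
                    assert single.lod == pytest.approx(multi.lod)

    def test_lod_oracle_all_n_up_to_20(self):
        # acceptance-grade closed-form vs brute-force equivalence
        for n in range(1, 21):
            for R in range(0, n + 1):
                Rmin = min(R, n - R)
                a = "0" * n
                b = "1" * R + "0" * (n - R)
                pl = pairwise_linkage(make_calls([a, b]), 0, 1)
                assert pl.lod == pytest.approx(brute_force_lod(n, Rmin), abs=1e-9)

    def test_lod_monotone_decreasing_in_rf(self):
        n = 100
        lods = [pairwise_linkage(make_calls(["0" * n, "1" * R + "0" * (n - R)]), 0, 1).lod
                for R in range(1, n // 2 + 1)]
        assert all(x > y for x, y in zip(lods, lods[1:]))
        assert lods[-1] == pytest.approx(0.0, abs=1e-12)


class TestGrouping:
    def test_two_chromosomes_recovered(self):
        genome = sim.simulate_genome(2, 8_000_000, seed=3)
        land = sim.plant_landscape(genome, 5.5)
        design = sim.CrossDesign(184, 0.0, 0.0, 20.0, 4)
        gm, _, truth = sim.simulate_cross(genome, land, 30.0, design, with_pileup=False)
        pairs = pairwise_all(gm.calls)
        groups, singletons = group_markers(pairs)
        assert len(groups) == 2 and not singletons
        tmap = truth.markers.set_index("marker_id")
        for group in groups:
            chroms = {tmap.loc[gm.markers[i].marker_id, "chrom"] for i in group}
            assert len(chroms) == 1

    def test_infinite_lod_all_singletons(self):
        calls = make_calls(["0101", "0101", "0110"])
        groups, singletons = group_markers(pairwise_all(calls), min_lod=float("inf"))
        assert not groups and singletons == [0, 1, 2]

    def test_marker_desert_splits_group(self):
        # two tight clusters separated by ~60 cM: below the LOD threshold
        rng = np.random.default_rng(9)
        n = 184
        left = rng.integers(0, 2, n).astype(np.int8)
        d_cm = 60.0
        r = haldane_r(d_cm)
        right = np.where(rng.random(n) < r, 1 - left, left).astype(np.int8)
        calls = np.vstack([np.tile(left, (5, 1)), np.tile(right, (5, 1))])
        groups, _ = group_markers(pairwise_all(calls))
        assert len(groups) == 2
        assert sorted(map(sorted, groups)) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]


class TestOrdering:
    def test_three_marker_additivity(self):
        rng = np.random.default_rng(2)
        n = 2000
        a = rng.integers(0, 2, n).astype(np.int8)
        b = np.where(rng.random(n) < 0.05, 1 - a, a).astype(np.int8)
        c = np.where(rng.random(n) < 0.05, 1 - b, b).astype(np.int8)
        calls = np.vstack([a, b, c])
        order = order_markers([0, 1, 2], pairwise_all(calls))
        assert order == [0, 1, 2]

    def test_group_of_two(self):
        calls = make_calls(["0011", "0010"])
        assert order_markers([0, 1], pairwise_all(calls)) == [0, 1]

    def test_canonical_reversal(self, small_cross, small_map):
        # first index smaller than last: reversal-equivalent orders are unique
        for group, order in zip(small_map["groups"], map(list, (g.markers for g in small_map["lmap"].groups))):
            assert order[0] < order[-1]

    def test_error_free_group_recovers_truth(self):
        genome = sim.simulate_genome(1, 5_000_000, seed=21)
        land = sim.plant_landscape(genome, 5.5)
        design = sim.CrossDesign(184, 0.0, 0.0, 20.0, 22)
        gm, _, truth = sim.simulate_cross(genome, land, 6.0, design, with_pileup=False)
        lmap, pairs, groups, _, _ = construct_map(gm.calls)
        assert len(lmap.groups) == 1
        lg = lmap.groups[0]
        tmap = truth.markers.set_index("marker_id")
        bp = tmap.loc[[gm.markers[i].marker_id for i in lg.markers], "chrom_pos"].to_numpy()
        # co-located markers (identical genotype columns) carry no ordering
        # information: compare distinct map positions via their mean true bp
        import pandas as pd

        mean_bp = pd.DataFrame({"cm": lg.positions_cm, "bp": bp}).groupby("cm")["bp"].mean()
        tau = kendalltau(mean_bp.index.to_numpy(), mean_bp.to_numpy()).statistic
        assert abs(tau) > 1 - 1e-9


class TestMasking:
    def test_isolated_flip_masked(self):
        # marker 1 carries a lone discordant genotype in individual 0;
        # n = 100 keeps the flanking genetic span below the masking gate
        n = 100
        base = "0" * (n - 2) + "11"
        flip = "1" + base[1:]
        calls = make_calls([base, flip, base, "0" * (n - 3) + "111"])
        pairs = pairwise_all(calls)
        masked, n_masked = mask_isolated_flips(calls, [0, 1, 2, 3], pairs)
        assert n_masked == 1
        assert masked[1, 0] == MISSING
        assert calls[1, 0] == 1  # input untouched

    def test_short_run_of_two_masked(self):
        # a double crossover spanning two adjacent bins is also masked
        n = 100
        base = "0" * n
        flip = "1" + "0" * (n - 1)
        tail = "0" * (n - 1) + "1"
        calls = make_calls([base, flip, flip[:-1] + "1", tail])
        # markers 1 and 2 differ (last individual), both carry ind-0 flip
        masked, n_masked = mask_isolated_flips(calls, [0, 1, 2, 3], pairwise_all(calls))
        assert masked[1, 0] == MISSING and masked[2, 0] == MISSING

    def test_wide_run_not_masked(self):
        # the same pattern with a wide genetic span stays untouched
        calls = make_calls(["0000000011", "1000000011", "0000000011", "0000000111"])
        _, n_masked = mask_isolated_flips(calls, [0, 1, 2, 3], pairwise_all(calls))
        assert n_masked == 0  # 1 mismatch in 10 meioses ~ 11 cM flanks

    def test_consistent_run_untouched(self):
        n = 100
        a = "0" * 50 + "1" * 50
        b = "0" * 49 + "1" * 51
        calls = make_calls([a, a, b])
        _, n_masked = mask_isolated_flips(calls, [0, 1, 2], pairwise_all(calls))
        assert n_masked == 0


class TestBuildMap:
    def test_prefix_sums(self):
        rng = np.random.default_rng(7)
        n = 184
        # construct three markers with adjacent rf exactly 0.1
        a = rng.integers(0, 2, n).astype(np.int8)
        b = a.copy(); b[: int(0.1 * n)] = 1 - b[: int(0.1 * n)]
        c = b.copy(); c[-int(0.1 * n):] = 1 - c[-int(0.1 * n):]
        calls = np.vstack([a, b, c])
        lmap = build_map(pairwise_all(calls), [[0, 1, 2]])
        d = haldane_cm(18 / 184)  # 0.1*184 rounds to 18 flipped calls
        assert lmap.groups[0].positions_cm == pytest.approx([0.0, d, 2 * d], abs=1e-9)

    def test_colocated_markers_zero_length(self):
        calls = make_calls(["0101", "0101", "0101"])
        lmap = build_map(pairwise_all(calls), [[0, 1, 2]])
        assert lmap.groups[0].length_cm == 0.0

    def test_positions_invariant_to_individual_relabeling(self, small_cross):
        gm = small_cross["gm"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(gm.calls.shape[1])
        lmap1, *_ = construct_map(gm.calls)
        lmap2, *_ = construct_map(gm.calls[:, perm])
        for g1, g2 in zip(lmap1.groups, lmap2.groups):
            assert g1.markers == g2.markers
            np.testing.assert_allclose(g1.positions_cm, g2.positions_cm, atol=1e-9)

    def test_reversal_leaves_length_unchanged(self, small_map):
        pairs = small_map["pairs"]
        for lg in small_map["lmap"].groups:
            rev = build_map(pairs, [list(reversed(lg.markers))])
            assert rev.groups[0].length_cm == pytest.approx(lg.length_cm, abs=1e-9)

    def test_map_length_recovery_dense(self):
        genome = sim.simulate_genome(1, 5_000_000, seed=31)
        land = sim.plant_landscape(genome, 20.0)  # 100 cM chromosome
        design = sim.CrossDesign(1000, 0.0, 0.0, 20.0, 32)
        gm, _, truth = sim.simulate_cross(genome, land, 40.0, design, with_pileup=False)
        lmap, *_ = construct_map(gm.calls)
        assert len(lmap.groups) == 1
        est = lmap.groups[0].length_cm
        # SE of the summed Haldane distances, plug-in estimate
        se = 100 * math.sqrt(land.total_cm("chr01") / 100 / design.n_progeny)
        assert abs(est - 100.0) < 3 * se + 1.0  # +1 cM end-truncation slack
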
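import numpy as np
import pandas as pd
import pytest

from radmap import landscape as ls
from radmap.anchor import assign_scaffolds, order_and_orient
from radmap.io import Gene
from radmap.landscape import (
    ChromProfile,
    ColdspotCall,
    HotspotCall,
    MareyProfile,
    _lnds_keep,
    associate,
    call_coldspots,
    call_hotspots,
    gene_density,
    genome_average_rate,
    marey_profile,
)


def profile_from(chrom_intervals):
    """chrom -> list of (start, end, dcm); builds a MareyProfile directly."""
    prof = MareyProfile()
    for chrom, ivs in chrom_intervals.items():
        df = pd.DataFrame(ivs, columns=["start", "end", "dcm"])
        df["rate"] = df["dcm"] / ((df["end"] - df["start"]) / 1e6)
        anchors = pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(len(ivs) + 1)],
            "bp": [ivs[0][0]] + [iv[1] for iv in ivs],
            "cm": np.concatenate([[0.0], np.cumsum(df["dcm"].to_numpy())]),
        })
        prof.chromosomes[chrom] = ChromProfile(chrom, anchors, df)
    return prof


def simple_assembly():
    t = pd.DataFrame(
        [
            ("LG1", "UM000001", "sA", 0, 0.0),
            ("LG1", "UM000002", "sA", 2_999_999, 30.0),
        ],
        columns=["group", "marker_id", "scaffold", "pos", "cm"],
    )
    return t, order_and_orient(assign_scaffolds(t), t, {"sA": 3_000_000}, gap=100)


class TestLnds:
    def test_keeps_ties(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0])
        np.testing.assert_array_equal(_lnds_keep(vals), [0, 1, 2, 3])

    def test_drops_outlier(self):
        vals = np.array([1.0, 2.0, 50.0, 3.0, 4.0])
        keep = _lnds_keep(vals)
        np.testing.assert_array_equal(keep, [0, 1, 3, 4])

    def test_monotone_input_untouched(self):
        vals = np.arange(10.0)
        assert len(_lnds_keep(vals)) == 10


class TestMareyProfile:
    def test_two_anchor_rate(self):
        t = pd.DataFrame(
            [
                ("LG1", "UM000001", "sA", 1_000_000, 10.0),
                ("LG1", "UM000002", "sA", 2_000_000, 20.0),
            ],
            columns=["group", "marker_id", "scaffold", "pos", "cm"],
        )
        asm = order_and_orient(assign_scaffolds(t), t, {"sA": 3_000_000}, gap=100)
        prof = marey_profile(t, asm)
        iv = prof.chromosomes["Chr1"].intervals
        assert len(iv) == 1
        assert iv["rate"].iloc[0] == pytest.approx(10.0)

    def test_outlier_removed(self):
        rows = [("LG1", f"UM{i:06d}", "sA", i * 100_000, float(i)) for i in range(1, 8)]
        rows[3] = ("LG1", "UM000004", "sA", 400_000, 100.0)  # discordant cM
        t = pd.DataFrame(rows, columns=["group", "marker_id", "scaffold", "pos", "cm"])
        asm = order_and_orient(assign_scaffolds(t), t, {"sA": 1_000_000}, gap=100)
        prof = marey_profile(t, asm)
        anchors = prof.chromosomes["Chr1"].anchors
        assert "UM000004" not in set(anchors["marker_id"])
        assert len(anchors) == 6

    def test_colocated_cm_zero_rate(self):
        t = pd.DataFrame(
            [
                ("LG1", "UM000001", "sA", 1_000_000, 5.0),
                ("LG1", "UM000002", "sA", 2_000_000, 5.0),
            ],
            columns=["group", "marker_id", "scaffold", "pos", "cm"],
        )
        asm = order_and_orient(assign_scaffolds(t), t, {"sA": 3_000_000}, gap=100)
        prof = marey_profile(t, asm)
        assert prof.chromosomes["Chr1"].intervals["rate"].iloc[0] == 0.0

    def test_single_anchor_chromosome_skipped(self):
        t = pd.DataFrame(
            [("LG1", "UM000001", "sA", 1_000, 0.0)],
            columns=["group", "marker_id", "scaffold", "pos", "cm"],
        )
        asm = order_and_orient(assign_scaffolds(t), t, {"sA": 3_000_000}, gap=100)
        prof = marey_profile(t, asm)
        assert prof.skipped == ["Chr1"] and not prof.chromosomes

    def test_reversed_map_direction_flipped(self):
        # cM decreasing along bp: profile flips the map, rates unchanged
        t, asm = simple_assembly()
        t_rev = t.copy()
        t_rev["cm"] = 30.0 - t_rev["cm"]
        p1 = marey_profile(t, asm)
        p2 = marey_profile(t_rev, asm)
        pd.testing.assert_frame_equal(
            p1.chromosomes["Chr1"].intervals, p2.chromosomes["Chr1"].intervals
        )

    def test_conservation_of_map_length(self, small_cross, small_map):
        from radmap.pipeline import map_table_from

        gm = small_cross["gm"]
        table = map_table_from(gm, small_map["lmap"])
        lengths = {s.scaffold_id: s.length for s in small_cross["scaffolds"]}
        asm = order_and_orient(assign_scaffolds(table), table, lengths)
        prof = marey_profile(table, asm)
        for chrom, cp in prof.chromosomes.items():
            span = cp.anchors["cm"].max() - cp.anchors["cm"].min()
            assert cp.intervals["dcm"].sum() == pytest.approx(span, abs=1e-9)


class TestGenomeAverage:
    def test_single_interval(self):
        prof = profile_from({"Chr1": [(0, 2_000_000, 10.0)]})
        assert genome_average_rate(prof) == pytest.approx(5.0)

    def test_length_weighting(self):
        prof = profile_from({"Chr1": [(0, 1_000_000, 10.0), (1_000_000, 10_000_000, 0.0)]})
        assert genome_average_rate(prof) == pytest.approx(1.0)

    def test_subdivision_invariance(self):
        coarse = profile_from({"Chr1": [(0, 4_000_000, 12.0)]})
        fine = profile_from({"Chr1": [(0, 1_000_000, 3.0), (1_000_000, 4_000_000, 9.0)]})
        assert genome_average_rate(coarse) == pytest.approx(genome_average_rate(fine))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            genome_average_rate(MareyProfile())


class TestHotspots:
    def test_rate_60_called_with_fold(self):
        prof = profile_from({"Chr1": [(0, 100_000, 6.0), (100_000, 200_000, 0.1)]})
        calls = call_hotspots(prof, avg=5.5, fold=10.0)
        assert len(calls) == 1
        h = calls[0]
        assert h.rate == pytest.approx(60.0)
        assert h.fold == pytest.approx(60.0 / 5.5, abs=1e-6)

    def test_boundary_strictly_greater(self):
        prof = profile_from({"Chr1": [(0, 100_000, 5.5)]})  # rate exactly 55
        assert call_hotspots(prof, avg=5.5, fold=10.0) == []

    def test_adjacent_intervals_merged(self):
        prof = profile_from({"Chr1": [(0, 100_000, 6.0), (100_000, 200_000, 7.0), (300_000, 400_000, 6.0)]})
        calls = call_hotspots(prof, avg=5.5, fold=10.0)
        assert [(c.start, c.end) for c in calls] == [(0, 200_000), (300_000, 400_000)]
        assert calls[0].rate == pytest.approx(65.0)

    def test_nonpositive_avg_rejected(self):
        with pytest.raises(ValueError):
            call_hotspots(MareyProfile(), avg=0.0)


class TestColdspots:
    def test_long_zero_run_called(self):
        prof = profile_from({"Chr1": [(0, 700_000, 0.0), (700_000, 1_500_000, 0.0), (1_500_000, 1_600_000, 1.0)]})
        calls = call_coldspots(prof, min_span_mb=1.0)
        assert len(calls) == 1
        assert calls[0].span_mb == pytest.approx(1.5)

    def test_short_zero_run_ignored(self):
        prof = profile_from({"Chr1": [(0, 800_000, 0.0), (800_000, 900_000, 1.0)]})
        assert call_coldspots(prof, min_span_mb=1.0) == []


class TestGeneDensity:
    def test_three_per_100kb(self):
        genes = [Gene("Chr1", i * 10, i * 10 + 5, f"g{i}") for i in range(3)]
        assert gene_density(genes, "Chr1", 0, 100_000) == 3.0

    def test_study_scale_density(self):
        # 28 902 genes over 1025.1 Mb -> 2.82 per 100 kb
        density = 28_902 / (1025.1e6 / 1e5)
        assert round(density, 2) == 2.82

    def test_empty_region_zero(self):
        assert gene_density([], "Chr1", 0, 100_000) == 0.0

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            gene_density([], "Chr1", 5, 5)


class TestAssociate:
    def test_percentage_of_dense_hotspots(self):
        genes = [Gene("Chr1", i, i + 1, f"g{i}") for i in range(400)]
        hot = [HotspotCall("Chr1", 0, 10_000, 100.0, 10.0)] * 0
        hot = [HotspotCall("Chr1", 0, 10_000, 100.0, 10.0) for _ in range(1)]
        hot += [HotspotCall("Chr2", 0, 10_000, 100.0, 10.0) for _ in range(1)]
        rep = associate(hot, [], genes, density_threshold=3.0)
        # 400 genes in 10 kb on Chr1 -> 4000/100kb; Chr2 empty
        assert rep["pct_hotspots_gene_dense"] == pytest.approx(50.0)
        assert rep["n_hotspot_genes"] == 400

    def test_empty_calls_marked_undefined(self):
        rep = associate([], [], [], genome_avg_density=2.82)
        assert rep["pct_hotspots_gene_dense"] is None
        assert rep["pct_coldspots_gene_sparse"] is None

    def test_coldspot_sparse_fraction(self):
        genes = [Gene("Chr1", i * 1000, i * 1000 + 10, f"g{i}") for i in range(100)]
        cold = [ColdspotCall("Chr1", 0, 2_000_000), ColdspotCall("Chr2", 0, 2_000_000)]
        rep = associate([], cold, genes, genome_avg_density=1.0)
        assert rep["n_coldspots_gene_sparse"] == 1
        assert rep["pct_coldspots_gene_sparse"] == pytest.approx(50.0)

    def test_directional_coupling_on_simulation(self):
        # crossover intensity planted in gene-dense windows: hotspot regions
        # must come out gene-denser than coldspot regions
        from radmap import linkage, sim
        from radmap.pipeline import map_table_from

        genome = sim.simulate_genome(4, 20_000_000, mean_gene_density=5e-5, seed=51)
        hot, cold = sim.hotspots_at_density_extremes(genome, 3, 200_000, 80.0, n_cold=1)
        land = sim.plant_landscape(genome, 5.5, hot, cold)
        design = sim.CrossDesign(184, 0.0, 0.0, 20.0, 52)
        scaffolds = sim.fragment_scaffolds(genome, 1_000_000, seed=53)
        gm, _, truth = sim.simulate_cross(
            genome, land, 30.0, design, scaffolds=scaffolds, with_pileup=False
        )
        lmap, pairs, groups, _, _ = linkage.construct_map(gm.calls)
        table = map_table_from(gm, lmap)
        lengths = {s.scaffold_id: s.length for s in scaffolds}
        asm = order_and_orient(assign_scaffolds(table), table, lengths)
        prof = marey_profile(table, asm)
        avg = genome_average_rate(prof)
        hotspots = call_hotspots(prof, avg)
        coldspots = call_coldspots(prof)
        from radmap.pipeline import lift_genes

        genes = lift_genes(genome.genes, scaffolds, asm)
        rep = associate(hotspots, coldspots, genes, genome_avg_density=5.0)
        assert hotspots and coldspots
        mean_hot = np.mean([h.gene_density for h in hotspots])
        mean_cold = np.mean([c.gene_density for c in coldspots])
        assert mean_hot > mean_cold


class TestReversalInvariance:
    def test_hotspots_invariant_under_group_reversal(self, small_cross, small_map):
        from radmap.pipeline import map_table_from

        gm = small_cross["gm"]
        table = map_table_from(gm, small_map["lmap"])
        lengths = {s.scaffold_id: s.length for s in small_cross["scaffolds"]}
        asm = order_and_orient(assign_scaffolds(table), table, lengths)
        prof1 = marey_profile(table, asm)
        avg1 = genome_average_rate(prof1)
        calls1 = call_hotspots(prof1, avg1)

        flipped = table.copy()
        for group, sub in table.groupby("group"):
            top = sub["cm"].max()
            flipped.loc[sub.index, "cm"] = top - sub["cm"]
        prof2 = marey_profile(flipped, asm)
        avg2 = genome_average_rate(prof2)
        calls2 = call_hotspots(prof2, avg2)
        assert avg1 == pytest.approx(avg2, abs=1e-9)
        assert {(c.chrom, c.start, c.end) for c in calls1} == {
            (c.chrom, c.start, c.end) for c in calls2
        }
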
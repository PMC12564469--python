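"""Signal-mapping rules against literal per-base / all-pairs oracles."""

import numpy as np
import pandas as pd
import pytest

import g4causal as g
from g4causal.mapping import (ValueTrack, assign_region_value, atac_intensity,
                              chrom_state_of_region, filter_regions_with_pg4,
                              mean_sequencing_depth, midpoint, phylop_of_pg4,
                              stability_of_pg4, tf_metrics)

import oracles



def assert_value_equal(a, b):
    """Equal up to float summation-order roundoff; NaN matches NaN."""
    if pd.isna(a) or pd.isna(b):
        assert pd.isna(a) and pd.isna(b)
    else:
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)

def row(**kw):
    return pd.DataFrame([kw]).itertuples().__next__()


def mm_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                       "value"])


class TestFilterRegions:
    def test_contained_pg4_keeps_region(self):
        regions = pd.DataFrame([("chr1", 100, 200, 1.0)],
                               columns=["chrom", "start", "end",
                                        "eg4_signal"])
        pg4s = pd.DataFrame([("chr1", 150, 180, "+")],
                            columns=["chrom", "start", "end", "strand"])
        assert len(filter_regions_with_pg4(regions, pg4s)) == 1

    def test_half_open_touching_intervals_do_not_overlap(self):
        regions = pd.DataFrame([("chr1", 100, 200, 1.0)],
                               columns=["chrom", "start", "end",
                                        "eg4_signal"])
        pg4s = pd.DataFrame([("chr1", 200, 230, "+")],
                            columns=["chrom", "start", "end", "strand"])
        assert len(filter_regions_with_pg4(regions, pg4s)) == 0

    def test_empty_inputs_give_empty_output(self):
        empty_r = pd.DataFrame(columns=["chrom", "start", "end"])
        empty_p = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        assert len(filter_regions_with_pg4(empty_r, empty_p)) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_scan(self, seed):
        fx = g.make_genome_fixture(seed=seed)
        ours = filter_regions_with_pg4(fx.regions, fx.pg4s)
        oracle = oracles.oracle_overlap_filter(fx.regions, fx.pg4s)
        pd.testing.assert_frame_equal(ours.reset_index(drop=True),
                                      oracle.reset_index(drop=True))


class TestStability:
    def test_same_strand_max_ignores_other_strand(self):
        track = ValueTrack(mm_frame([
            ("chr1", 100, 110, "+", 3.0), ("chr1", 120, 130, "+", 27.5),
            ("chr1", 140, 150, "+", 11.2), ("chr1", 100, 150, "-", 99.0)]),
            stranded=True)
        pg4 = row(chrom="chr1", start=120, end=130, strand="+")
        assert stability_of_pg4(pg4, track) == pytest.approx(27.5)

    def test_strand_mismatch_gives_missing(self):
        track = ValueTrack(mm_frame([("chr1", 100, 150, "-", 40.0)]),
                           stranded=True)
        pg4 = row(chrom="chr1", start=120, end=130, strand="+")
        assert np.isnan(stability_of_pg4(pg4, track))

    def test_singleton_value(self):
        track = ValueTrack(mm_frame([("chr1", 120, 121, "+", 25.0)]),
                           stranded=True)
        pg4 = row(chrom="chr1", start=118, end=124, strand="+")
        assert stability_of_pg4(pg4, track) == pytest.approx(25.0)

    def test_window_is_150bp_centred_half_open(self):
        # midpoint 1000 -> window [925, 1075)
        mid = 1000
        inside = ValueTrack(mm_frame([("chr1", 1074, 1080, "+", 60.0)]),
                            stranded=True)
        outside = ValueTrack(mm_frame([("chr1", 1075, 1080, "+", 60.0)]),
                             stranded=True)
        pg4 = row(chrom="chr1", start=mid - 5, end=mid + 5, strand="+")
        assert stability_of_pg4(pg4, inside) == pytest.approx(60.0)
        assert np.isnan(stability_of_pg4(pg4, outside))


class TestPhylop:
    def test_mean_of_covered_positions(self):
        track = ValueTrack(pd.DataFrame(
            [("chr1", 100, 101, 1.0), ("chr1", 105, 106, 3.0)],
            columns=["chrom", "start", "end", "value"]))
        pg4 = row(chrom="chr1", start=100, end=106, strand="+")
        assert phylop_of_pg4(pg4, track) == pytest.approx(2.0)

    def test_uncovered_window_missing(self):
        track = ValueTrack(pd.DataFrame(
            [("chr2", 0, 10, 1.0)], columns=["chrom", "start", "end",
                                             "value"]))
        pg4 = row(chrom="chr1", start=100, end=106, strand="+")
        assert np.isnan(phylop_of_pg4(pg4, track))

    def test_mean_is_coverage_weighted(self):
        # 10 bases at 1.0, 5 bases at 4.0 inside the 50bp window
        track = ValueTrack(pd.DataFrame(
            [("chr1", 990, 1000, 1.0), ("chr1", 1000, 1005, 4.0)],
            columns=["chrom", "start", "end", "value"]))
        pg4 = row(chrom="chr1", start=995, end=1005, strand="+")
        assert phylop_of_pg4(pg4, track) == pytest.approx((10 + 20) / 15)


class TestRegionAssignment:
    def pg4s(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                           "value"])

    def test_nearest_midpoint_wins(self):
        region = row(chrom="chr1", start=100, end=200)
        # region midpoint 150; pG4 midpoints 162 (d=12) and 110 (d=40)
        cands = self.pg4s([("chr1", 157, 167, "+", 1.0),
                           ("chr1", 105, 115, "+", 2.0)])
        assert assign_region_value(region, cands) == pytest.approx(1.0)

    def test_single_overlapping_candidate(self):
        region = row(chrom="chr1", start=100, end=200)
        cands = self.pg4s([("chr1", 190, 210, "+", 7.0)])
        assert assign_region_value(region, cands) == pytest.approx(7.0)

    def test_equidistant_tie_breaks_to_lower_start(self):
        region = row(chrom="chr1", start=100, end=200)
        cands = self.pg4s([("chr1", 155, 165, "+", 1.0),
                           ("chr1", 135, 145, "+", 2.0)])  # both d=10
        assert assign_region_value(region, cands) == pytest.approx(2.0)

    def test_non_overlapping_pg4_never_assigns(self):
        region = row(chrom="chr1", start=100, end=200)
        cands = self.pg4s([("chr1", 300, 320, "+", 9.0)])
        assert np.isnan(assign_region_value(region, cands))

    def test_candidates_without_values_are_skipped(self):
        region = row(chrom="chr1", start=100, end=200)
        cands = self.pg4s([("chr1", 145, 155, "+", np.nan),
                           ("chr1", 110, 120, "+", 5.0)])
        assert assign_region_value(region, cands) == pytest.approx(5.0)


class TestChromState:
    def segmentation(self):
        return pd.DataFrame(
            [("chr1", 100, 200, "TssA"), ("chr1", 200, 300, "Quies")],
            columns=["chrom", "start", "end", "state"])

    def test_midpoint_containment(self):
        region = row(chrom="chr1", start=120, end=180)  # midpoint 150
        assert chrom_state_of_region(region, self.segmentation()) == "TssA"

    def test_boundary_midpoint_takes_right_segment(self):
        region = row(chrom="chr1", start=150, end=250)  # midpoint 200
        assert chrom_state_of_region(region, self.segmentation()) == "Quies"

    def test_unsegmented_midpoint_is_missing(self):
        region = row(chrom="chr1", start=350, end=450)
        assert pd.isna(chrom_state_of_region(region, self.segmentation()))

    def test_overlapping_segments_rejected(self):
        seg = pd.DataFrame(
            [("chr1", 100, 220, "TssA"), ("chr1", 200, 300, "Quies")],
            columns=["chrom", "start", "end", "state"])
        region = row(chrom="chr1", start=120, end=180)
        with pytest.raises(ValueError, match="overlap"):
            chrom_state_of_region(region, seg)


class TestAtac:
    def frags(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_hand_coverage(self):
        region = row(chrom="chr1", start=0, end=100)
        frags = self.frags([("chr1", 0, 50)])
        assert atac_intensity(region, frags, 1.0) == pytest.approx(0.5)

    def test_no_fragments_zero(self):
        region = row(chrom="chr1", start=0, end=100)
        assert atac_intensity(region, self.frags([]), 1.0) == 0.0

    def test_depth_scaling(self):
        region = row(chrom="chr1", start=0, end=100)
        frags = self.frags([("chr1", 10, 60), ("chr1", 40, 90)])
        one = atac_intensity(region, frags, 1.0)
        assert atac_intensity(region, frags, 2.0) == pytest.approx(one / 2)

    def test_nonpositive_depth_rejected(self):
        region = row(chrom="chr1", start=0, end=100)
        with pytest.raises(ValueError):
            atac_intensity(region, self.frags([]), 0.0)

    def test_mean_depth_helper_counts_fragment_bases(self):
        frags = self.frags([("chr1", 0, 50), ("chr2", 0, 150)])
        assert mean_sequencing_depth(frags, {"chr1": 100, "chr2": 100}) \
            == pytest.approx(1.0)


class TestTfMetrics:
    def peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf"])

    def test_hand_counts_and_total_recruitment(self):
        region = row(chrom="chr1", start=100, end=200)
        peaks = self.peaks([("chr1", 90, 120, "SP1"),
                            ("chr1", 150, 160, "SP1"),
                            ("chr1", 180, 250, "YY1"),
                            ("chr2", 100, 200, "SP1")])
        occ, rec = tf_metrics(region, peaks)
        assert occ == {"SP1": 2, "YY1": 1} and rec == 3

    def test_distinct_mode_counts_tfs(self):
        region = row(chrom="chr1", start=100, end=200)
        peaks = self.peaks([("chr1", 90, 120, "SP1"),
                            ("chr1", 150, 160, "SP1"),
                            ("chr1", 180, 250, "YY1")])
        _, rec = tf_metrics(region, peaks, recruitment="distinct")
        assert rec == 2

    def test_no_overlap_empty(self):
        region = row(chrom="chr1", start=100, end=200)
        occ, rec = tf_metrics(region, self.peaks([("chr1", 300, 400,
                                                   "SP1")]))
        assert occ == {} and rec == 0


class TestBuildRegionTable:
    def test_composition_matches_per_metric_oracles(self, genome_fixture,
                                                    region_table):
        fx = genome_fixture
        depth = mean_sequencing_depth(fx.atac_fragments, fx.chrom_sizes)
        stab = [oracles.oracle_stability(p, fx.mm_track)
                for p in fx.pg4s.itertuples()]
        phy = [oracles.oracle_phylop(p, fx.phylop_track)
               for p in fx.pg4s.itertuples()]
        kept = oracles.oracle_overlap_filter(fx.regions, fx.pg4s)
        assert list(region_table.region_id) == list(kept.region_id)
        for i, r in enumerate(kept.itertuples()):
            got = region_table.iloc[i]
            assert_value_equal(
                got.stability, oracles.oracle_region_assign(r, fx.pg4s, stab))
            assert_value_equal(
                got.phylop, oracles.oracle_region_assign(r, fx.pg4s, phy))
            assert got.chrom_state == oracles.oracle_chrom_state(
                r, fx.segmentation)
            assert got.atac == pytest.approx(
                oracles.oracle_atac(r, fx.atac_fragments, depth))
            occ, rec = oracles.oracle_tf_metrics(r, fx.tf_peaks)
            assert got.tf_recruitment == rec
            for tf in fx.tf_peaks.tf.unique():
                assert got[f"occ_{tf}"] == occ.get(tf, 0)

    def test_zero_decoys_keeps_every_region(self):
        fx = g.make_genome_fixture(seed=2, config=g.FixtureConfig(
            n_decoys=0))
        table = g.build_region_table(fx)
        assert len(table) == len(fx.regions)

    def test_empty_region_set_gives_schema_only(self, genome_fixture):
        import dataclasses
        fx = dataclasses.replace(
            genome_fixture, regions=genome_fixture.regions.iloc[0:0])
        table = g.build_region_table(fx)
        assert len(table) == 0
        assert {"stability", "eg4_signal", "atac", "phylop", "chrom_state",
                "tf_recruitment", "stratum"} <= set(table.columns)


class TestSymmetryProperties:
    def shift_fixture(self, fx, delta):
        import dataclasses
        out = {}
        for name in ("pg4s", "mm_track", "phylop_track", "segmentation",
                     "atac_fragments", "tf_peaks", "regions"):
            df = getattr(fx, name).copy()
            df["start"] += delta
            df["end"] += delta
            out[name] = df
        tss = fx.tss.copy()
        tss["pos"] += delta
        sizes = {c: s + delta for c, s in fx.chrom_sizes.items()}
        return dataclasses.replace(fx, chrom_sizes=sizes, tss=tss, **out)

    def test_translation_invariance(self, genome_fixture, region_table):
        shifted = self.shift_fixture(genome_fixture, 500)
        depth = mean_sequencing_depth(genome_fixture.atac_fragments,
                                      genome_fixture.chrom_sizes)
        shifted_table = g.build_region_table(shifted, mean_depth=depth)
        base = g.build_region_table(genome_fixture, mean_depth=depth)
        cols = ["stability", "eg4_signal", "atac", "phylop", "chrom_state",
                "tf_recruitment"]
        pd.testing.assert_frame_equal(shifted_table[cols], base[cols])

    def test_strand_flip_leaves_stability_unchanged(self, genome_fixture,
                                                    region_table):
        import dataclasses
        flip = {"+": "-", "-": "+"}
        pg4s = genome_fixture.pg4s.copy()
        pg4s["strand"] = pg4s.strand.map(flip)
        mm = genome_fixture.mm_track.copy()
        mm["strand"] = mm.strand.map(flip)
        flipped = dataclasses.replace(genome_fixture, pg4s=pg4s, mm_track=mm)
        flipped_table = g.build_region_table(flipped)
        pd.testing.assert_series_equal(flipped_table.stability,
                                       region_table.stability)


@pytest.mark.parametrize("seed", range(40))
def test_randomized_fixture_oracle_equivalence(seed):
    """Mapping agrees exactly with per-base oracles on random fixtures."""
    fx = g.make_genome_fixture(seed=10_000 + seed)
    table = g.build_region_table(fx)
    depth = mean_sequencing_depth(fx.atac_fragments, fx.chrom_sizes)
    stab = [oracles.oracle_stability(p, fx.mm_track)
            for p in fx.pg4s.itertuples()]
    kept = oracles.oracle_overlap_filter(fx.regions, fx.pg4s)
    for i, r in enumerate(kept.itertuples()):
        got = table.iloc[i]
        assert_value_equal(got.stability,
                           oracles.oracle_region_assign(r, fx.pg4s, stab))
        assert got.chrom_state == oracles.oracle_chrom_state(
            r, fx.segmentation)
        assert got.atac == pytest.approx(
            oracles.oracle_atac(r, fx.atac_fragments, depth))


def test_midpoint_is_floor_convention():
    assert midpoint(0, 3) == 1
    assert midpoint(100, 200) == 150
    assert midpoint(5, 6) == 5
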
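import numpy as np
import pandas as pd
import pytest

from flankfda.windows import (
    DEFAULT_LENGTH_BOUNDS,
    ElementRecord,
    PlacementError,
    build_flanks,
    distance_to_landmarks,
    filter_elements,
    impute_missing,
    make_controls,
    merge_intervals,
    overlap_bp,
    quantify_content,
    quantify_count,
    quantify_scalar_wa,
    quantify_wa,
    read_bed,
    read_bedgraph,
    write_elements,
    read_elements,
)
from oracles import count_starts, per_base_content, per_base_wa

SIZES = {"chr1": 1_000_000, "chr2": 500_000}


def elem(start, end, strand="+", chrom="chr1", id="e1", cls="fixed"):
    return ElementRecord(chrom=chrom, start=start, end=end, strand=strand,
                         class_label=cls, id=id)


class TestElementRecord:
    def test_rejects_inverted_coords(self):
        with pytest.raises(ValueError, match="start"):
            elem(100, 100)

    def test_rejects_bad_strand(self):
        with pytest.raises(ValueError, match="strand"):
            elem(0, 10, strand=".")

    def test_rejects_bad_class(self):
        with pytest.raises(ValueError, match="class"):
            elem(0, 10, cls="other")

    def test_bed_round_trip(self, tmp_path):
        elems = [elem(100_000, 101_000, id="a"),
                 elem(200_000, 200_500, strand="-", id="b", cls="control")]
        path = tmp_path / "e.bed"
        write_elements(elems, path)
        assert read_elements(path) == elems


class TestBuildFlanks:
    def test_plus_strand_window_definition(self):
        flanks, _ = build_flanks([elem(100_000, 101_000)], SIZES)
        fw = flanks[0]
        assert fw.n_windows == 64
        # window -1 (index 31) abuts the start, +1 (index 32) abuts the end
        assert (fw.starts[31], fw.starts[31] + 1000) == (99_000, 100_000)
        assert (fw.starts[32], fw.starts[32] + 1000) == (101_000, 102_000)
        assert fw.starts[0] == 100_000 - 32_000

    def test_minus_strand_inverted(self):
        flanks, _ = build_flanks([elem(100_000, 101_000, strand="-")], SIZES)
        fw = flanks[0]
        assert (fw.starts[32], fw.starts[32] + 1000) == (99_000, 100_000)
        assert (fw.starts[31], fw.starts[31] + 1000) == (101_000, 102_000)

    def test_orientation_involution(self):
        plus, _ = build_flanks([elem(100_000, 101_000)], SIZES)
        minus, _ = build_flanks([elem(100_000, 101_000, strand="-")], SIZES)
        np.testing.assert_array_equal(minus[0].starts[::-1], plus[0].starts)

    def test_no_orient_keeps_genomic_order(self):
        flanks, _ = build_flanks([elem(100_000, 101_000, strand="-")], SIZES,
                                 orient=False)
        assert (np.diff(flanks[0].starts) > 0).all()

    def test_near_chromosome_start_dropped(self):
        flanks, dropped = build_flanks([elem(500, 1_500, id="edge")], SIZES)
        assert flanks == []
        assert dropped == [("edge", "flank_out_of_bounds")]

    def test_near_chromosome_end_dropped(self):
        flanks, dropped = build_flanks(
            [elem(499_000, 499_500, chrom="chr2", id="edge")], SIZES
        )
        assert dropped == [("edge", "flank_out_of_bounds")]

    def test_unknown_chromosome_dropped(self):
        _, dropped = build_flanks([elem(100_000, 101_000, chrom="chr9")], SIZES)
        assert dropped == [("e1", "unknown_chromosome")]

    def test_configurable_geometry(self):
        flanks, _ = build_flanks([elem(100_000, 101_000)], SIZES,
                                 flank_kb=4, window_kb=2)
        assert flanks[0].n_windows == 4
        assert flanks[0].window_bp == 2000


class TestFilterElements:
    def test_gap_overlap_excluded(self):
        gaps = pd.DataFrame({"chrom": ["chr1"], "start": [99_000], "end": [99_400]})
        res = filter_elements([elem(130_000, 131_000)], gap_track=gaps)
        # upstream flank [98_000, 130_000) overlaps the 400-bp gap entirely
        assert res.retained == []
        assert res.report.iloc[0]["rule"] == "gap_overlap"

    def test_gap_under_threshold_retained(self):
        gaps = pd.DataFrame({"chrom": ["chr1"], "start": [99_000], "end": [99_300]})
        res = filter_elements([elem(130_000, 131_000)], gap_track=gaps)
        assert len(res.retained) == 1

    def test_flank_overlap_excludes_both(self):
        # [DERIVED] interval arithmetic: spans 63 kb apart overlap by ~1 kb
        a = elem(100_000, 101_000, id="a")
        b = elem(163_000, 164_000, id="b")
        res = filter_elements([a, b])
        assert res.retained == []
        assert set(res.report["element_id"]) == {"a", "b"}
        assert (res.report["rule"] == "flank_overlap").all()

    def test_isolated_element_retained(self):
        res = filter_elements([elem(100_000, 101_000)])
        assert len(res.retained) == 1
        assert res.report.empty

    def test_one_bp_overlap_allowed(self):
        # spans overlapping by exactly 1 bp survive the > 1 bp rule
        a = elem(100_000, 101_000, id="a")
        b = elem(164_999, 166_000, id="b")  # spans [68k,133k) and [132.999k,198k)
        res = filter_elements([a, b])
        assert len(res.retained) == 2

    def test_length_bounds(self):
        short = elem(100_000, 100_030, id="short")
        long = elem(100_000, 120_000, id="long", chrom="chr2")
        res = filter_elements([short, long])
        assert res.retained == []
        assert set(res.report["rule"]) == {"length_out_of_bounds"}
        assert DEFAULT_LENGTH_BOUNDS == (60, 11_000)

    def test_chry_excluded_by_default(self):
        res = filter_elements([elem(100_000, 101_000, chrom="chrY")])
        assert res.report.iloc[0]["rule"] == "excluded_chromosome"
        assert filter_elements(
            [elem(100_000, 101_000, chrom="chrY")], exclude_chroms=()
        ).retained != []


class TestControls:
    def test_empty_ltr_track_places_all(self):
        controls = make_controls(SIZES, None, [], n_controls=5, seed=1)
        assert len(controls) == 5
        assert all(c.class_label == "control" for c in controls)
        assert all(c.end - c.start == 64_000 for c in controls)

    def test_full_coverage_errors_with_count(self):
        ltr = pd.DataFrame({"chrom": list(SIZES), "start": [0, 0],
                            "end": [SIZES["chr1"], SIZES["chr2"]]})
        with pytest.raises(PlacementError) as exc:
            make_controls(SIZES, ltr, [], n_controls=3, seed=1,
                          max_attempts_per_control=50)
        assert exc.value.achieved == 0

    def test_reproducible(self):
        a = make_controls(SIZES, None, [], n_controls=4, seed=9)
        b = make_controls(SIZES, None, [], n_controls=4, seed=9)
        assert a == b

    def test_mutually_non_overlapping(self):
        controls = make_controls({"chr1": 1_000_000}, None, [], n_controls=5, seed=3)
        spans = sorted((c.start, c.end) for c in controls)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_ltr_fraction_respected_per_base_oracle(self):
        # [DERIVED] verify every placement against a per-base overlap count
        rng = np.random.default_rng(5)
        # dense LTRs over the first half of the chromosome only, so that
        # admissible placements exist and the constraint actually binds
        starts = np.sort(rng.integers(0, 490_000, size=120))
        ltr = pd.DataFrame({"chrom": "chr1", "start": starts,
                            "end": starts + rng.integers(2000, 6000, size=120)})
        controls = make_controls({"chr1": 1_000_000}, ltr, [], n_controls=3,
                                 max_ltr_fraction=0.02, seed=7,
                                 max_attempts_per_control=20_000)
        ivs = list(zip(ltr["start"], ltr["end"]))
        for c in controls:
            frac = per_base_content(ivs, c.start, c.end)
            assert frac <= 0.02

    def test_flank_span_avoidance(self):
        spans = [("chr1", 0, 900_000)]
        controls = make_controls(SIZES, None, spans, n_controls=3, seed=2)
        for c in controls:
            if c.chrom == "chr1":
                ov = min(c.end, 900_000) - max(c.start, 0)
                assert ov <= 0.01 * 64_000


def _flanks_for(elements, **kw):
    flanks, dropped = build_flanks(elements, SIZES, **kw)
    assert not dropped
    return flanks


class TestQuantifyContent:
    def test_quarter_coverage(self):
        flanks = _flanks_for([elem(132_000, 133_000)], flank_kb=32)
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100_100], "end": [100_350]})
        cm = quantify_content(track, flanks)
        assert cm.values[0, 0] == pytest.approx(0.25)

    def test_overlapping_intervals_merged(self):
        flanks = _flanks_for([elem(132_000, 133_000)], flank_kb=32)
        track = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [100_000, 100_400],
                              "end": [100_600, 101_000]})
        cm = quantify_content(track, flanks)
        assert cm.values[0, 0] == pytest.approx(1.0)

    def test_random_intervals_match_per_base_oracle(self):
        # [DERIVED] 200 random intervals vs boolean-array coverage
        rng = np.random.default_rng(11)
        flanks = _flanks_for([elem(132_000, 133_000),
                              elem(400_000, 401_000, strand="-", id="e2")])
        starts = rng.integers(90_000, 440_000, size=200)
        track = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + rng.integers(1, 3000, size=200)})
        cm = quantify_content(track, flanks)
        ivs = list(zip(track["start"], track["end"]))
        for i, fw in enumerate(flanks):
            for w in range(fw.n_windows):
                expected = per_base_content(ivs, fw.starts[w], fw.starts[w] + 1000)
                assert cm.values[i, w] == pytest.approx(expected), (i, w)

    def test_sum_rule_with_complement(self):
        # content of track + content of its complement = 1 everywhere
        rng = np.random.default_rng(12)
        flanks = _flanks_for([elem(132_000, 133_000)])
        s = np.sort(rng.choice(np.arange(90_000, 180_000, 7), 40, replace=False))
        track = pd.DataFrame({"chrom": "chr1", "start": s, "end": s + 5})
        ms, me = merge_intervals(s, s + 5)
        comp_s = np.concatenate([[0], me])
        comp_e = np.concatenate([ms, [1_000_000]])
        comp = pd.DataFrame({"chrom": "chr1", "start": comp_s, "end": comp_e})
        total = quantify_content(track, flanks).values + quantify_content(comp, flanks).values
        np.testing.assert_allclose(total, 1.0)

    def test_empty_track_all_zero(self):
        flanks = _flanks_for([elem(132_000, 133_000)])
        cm = quantify_content(pd.DataFrame(columns=["chrom", "start", "end"]), flanks)
        assert (cm.values == 0).all()


class TestQuantifyCount:
    def test_motifs_inside_window(self):
        flanks = _flanks_for([elem(132_000, 133_000)])
        track = pd.DataFrame({"chrom": "chr1",
                              "start": [100_100, 100_500, 100_900],
                              "end": [100_110, 100_510, 100_910]})
        cm = quantify_count(track, flanks)
        assert cm.values[0, 0] == 3

    def test_boundary_straddler_counted_once_at_start(self):
        flanks = _flanks_for([elem(132_000, 133_000)])
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100_995], "end": [101_005]})
        cm = quantify_count(track, flanks)
        assert cm.values[0, 0] == 1
        assert cm.values[0, 1] == 0
        assert cm.values.sum() == 1

    def test_random_motifs_match_binning_oracle(self):
        rng = np.random.default_rng(13)
        flanks = _flanks_for([elem(132_000, 133_000, strand="-")])
        starts = rng.integers(95_000, 170_000, size=300)
        track = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 10})
        cm = quantify_count(track, flanks)
        ivs = list(zip(track["start"], track["end"]))
        fw = flanks[0]
        for w in range(64):
            assert cm.values[0, w] == count_starts(ivs, fw.starts[w], fw.starts[w] + 1000)

    def test_count_conservation(self):
        # total over all windows equals the count over the whole span
        rng = np.random.default_rng(14)
        flanks = _flanks_for([elem(132_000, 133_000)])
        fw = flanks[0]
        lo, hi = fw.span()
        starts = rng.integers(lo, hi, size=500)
        track = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 1})
        cm = quantify_count(track, flanks)
        in_element = ((starts >= 132_000) & (starts < 133_000)).sum()
        assert cm.values.sum() == 500 - in_element


class TestQuantifyWA:
    def test_weighted_average_arithmetic(self):
        flanks = _flanks_for([elem(132_000, 133_000)])
        track = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [100_000, 100_300],
                              "end": [100_300, 100_400],
                              "value": [2.0, 4.0]})
        cm = quantify_wa(track, flanks)
        assert cm.values[0, 0] == pytest.approx(2.5)

    def test_uniform_value_identity(self):
        flanks = _flanks_for([elem(132_000, 133_000)])
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000],
                              "value": [7.25]})
        cm = quantify_wa(track, flanks)
        np.testing.assert_allclose(cm.values, 7.25)

    def test_random_valued_intervals_match_per_base_oracle(self):
        rng = np.random.default_rng(15)
        flanks = _flanks_for([elem(132_000, 133_000)])
        starts = rng.integers(95_000, 170_000, size=200)
        track = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + rng.integers(1, 2500, size=200),
                              "value": rng.normal(size=200)})
        cm = quantify_wa(track, flanks)
        recs = list(zip(track["start"], track["end"], track["value"]))
        fw = flanks[0]
        for w in range(64):
            expected = per_base_wa(recs, fw.starts[w], fw.starts[w] + 1000)
            if np.isnan(expected):
                assert np.isnan(cm.values[0, w])
            else:
                assert cm.values[0, w] == pytest.approx(expected), w

    def test_missing_windows_flagged_and_imputed(self):
        flanks = _flanks_for([elem(132_000, 133_000)])
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100_000],
                              "end": [101_000], "value": [3.0]})
        cm = quantify_wa(track, flanks)
        assert cm.values[0, 0] == 3.0
        assert np.isnan(cm.values[0, 1:]).all()
        imputed = impute_missing(cm)
        np.testing.assert_allclose(imputed.values, 3.0)

    def test_impute_all_missing_raises(self):
        flanks = _flanks_for([elem(132_000, 133_000)])
        cm = quantify_wa(pd.DataFrame(columns=["chrom", "start", "end", "value"]),
                         flanks)
        with pytest.raises(ValueError, match="no data"):
            impute_missing(cm)


class TestScalars:
    def test_constant_track_gives_constant(self):
        flanks = _flanks_for([elem(132_000, 133_000)])
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000],
                              "value": [0.42]})
        table = quantify_scalar_wa(track, flanks, "rate")
        assert table.values[0] == pytest.approx(0.42)

    def test_random_track_matches_whole_region_oracle(self):
        rng = np.random.default_rng(16)
        flanks = _flanks_for([elem(132_000, 133_000)])
        starts = rng.integers(90_000, 175_000, size=80)
        track = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + rng.integers(500, 4000, size=80),
                              "value": rng.normal(size=80)})
        table = quantify_scalar_wa(track, flanks, "rate")
        recs = list(zip(track["start"], track["end"], track["value"]))
        # whole-region oracle: per-base accumulation over both flanks,
        # excluding the element body [132000, 133000)
        num = den = 0.0
        for lo, hi in [(100_000, 132_000), (133_000, 165_000)]:
            for s, e, v in recs:
                ov = min(e, hi) - max(s, lo)
                if ov > 0:
                    num += v * ov
                    den += ov
        assert table.values[0] == pytest.approx(num / den)

    def test_distance_zero_at_landmark(self):
        e = elem(100_000, 101_000)
        table = distance_to_landmarks([e], {"chr1": np.array([100_500])})
        assert table.values[0] == 0

    def test_nearest_landmark(self):
        e = elem(100_000, 101_000)
        table = distance_to_landmarks([e], {"chr1": np.array([0, 90_000, 500_000])})
        assert table.values[0] == 10_500


class TestIO:
    def test_malformed_bed_reports_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t20\nchr1\t50\t40\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(path)

    def test_bedgraph_rejects_nonfinite(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chr1\t0\t10\tinf\n")
        with pytest.raises(ValueError, match="non-finite"):
            read_bedgraph(path)

    def test_overlap_bp_helper(self):
        s, e = merge_intervals(np.array([0, 5, 20]), np.array([10, 12, 30]))
        np.testing.assert_array_equal(s, [0, 20])
        np.testing.assert_array_equal(e, [12, 30])
        assert overlap_bp(s, e, np.array([8]), np.array([25]))[0] == 4 + 5
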
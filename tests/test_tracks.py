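import numpy as np
import pytest

from siqchip.tracks import (EfficiencyTrack, Efficiency2D, FragmentSet,
                            GeometryError, bin2d, differential, efficiency2d,
                            efficiency_profile, project1d, read_bedgraph,
                            read_fragments, stabilize_width, write_bedgraph)


def make_fragments(records):
    chroms, starts, lengths = zip(*records)
    return FragmentSet(np.array(chroms, dtype=object), np.array(starts),
                       np.array(lengths))


class TestReadFragments:
    def test_basic_line(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("chr1\t100\t250\n")
        frags = read_fragments(path)
        assert len(frags) == 1
        assert frags.starts[0] == 100 and frags.lengths[0] == 150

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.bed"
        path.write_text("")
        with caplog.at_level("WARNING"):
            frags = read_fragments(path)
        assert len(frags) == 0
        assert any("no fragments" in r.message for r in caplog.records)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t100\nchr1\tfoo\tbar\n")
        with pytest.raises(ValueError, match=":2"):
            read_fragments(path)

    def test_inverted_intervals_skipped_and_counted(self, tmp_path):
        path = tmp_path / "inv.bed"
        path.write_text("chr1\t100\t50\nchr1\t0\t10\nchr2\t5\t5\n")
        frags = read_fragments(path)
        assert len(frags) == 1 and frags.skipped == 2

    def test_single_end_constant_length(self, tmp_path):
        path = tmp_path / "se.bed"
        path.write_text("chr1\t100\t101\nchr1\t500\t501\n")
        frags = read_fragments(path, constant_length=147)
        assert np.all(frags.lengths == 147)

    def test_synthetic_fixture_matches_generator_ledger(self, generated_pair,
                                                        tmp_path):
        exp = generated_pair[10_000]
        from siqchip.synthetic import _write_bed
        path = tmp_path / "gen.bed"
        _write_bed(exp.ip, path)
        frags = read_fragments(path)
        assert len(frags) == sum(exp.ledger.bound_fragments.values())
        assert frags.lengths.sum() == exp.ip.lengths.sum()


class TestBin2d:
    def test_floor_assignment(self):
        track = bin2d(make_fragments([("chr1", 100, 150)]), 1000, 50)
        assert track.data["chr1"][0, 3] == 1
        assert track.total() == 1

    def test_rebinning_merges_pairs_and_conserves_counts(self):
        rng = np.random.default_rng(7)
        frags = make_fragments([("chr1", int(s), int(l)) for s, l in zip(
            rng.integers(0, 100_000, 500), rng.integers(60, 400, 500))])
        fine = bin2d(frags, 1000, 50)
        coarse = bin2d(frags, 2000, 50)
        assert fine.total() == coarse.total() == 500
        fx = fine.marginal_x("chr1")
        cx = coarse.marginal_x("chr1")
        paired = np.add.reduceat(fx, np.arange(0, len(fx), 2))
        assert np.array_equal(paired, cx[: len(paired)])

    def test_length_marginal_matches_independent_counter(self):
        rng = np.random.default_rng(11)
        starts = rng.integers(0, 50_000, 10_000)
        lengths = rng.integers(50, 500, 10_000)
        frags = make_fragments([("chr1", int(s), int(l))
                                for s, l in zip(starts, lengths)])
        track = bin2d(frags, 1000, 10)
        # single-pass 1D start histogram, independent of the 2D path
        expected = np.bincount(starts // 1000)
        assert np.array_equal(track.marginal_x("chr1"), expected)

    def test_invalid_widths(self):
        with pytest.raises(ValueError):
            bin2d(make_fragments([("chr1", 0, 100)]), 0, 10)


def simple_e2d(ip, inp, alpha=1.0, width=1000, lwidth=50):
    return efficiency2d(bin2d(make_fragments(ip), width, lwidth),
                        bin2d(make_fragments(inp), width, lwidth), alpha)


class TestEfficiency2d:
    def test_identical_tracks_give_unity(self):
        recs = [("chr1", 100, 150), ("chr1", 1200, 200), ("chr2", 0, 100)]
        e2d = simple_e2d(recs, recs, alpha=1.0)
        for chrom in e2d.values:
            vals = e2d.values[chrom]
            assert np.all(vals[e2d.ip_counts[chrom] > 0] == 1.0)

    def test_zero_rule_and_flagging(self):
        ip = [("chr1", 100, 100)] * 5
        inp = [("chr1", 1100, 100)] * 3
        e2d = simple_e2d(ip, inp)
        assert e2d.values["chr1"][0, 2] == 0.0      # ip only: zero
        assert e2d.flags["chr1"][0, 2]              # ... and flagged
        assert e2d.values["chr1"][1, 2] == 0.0      # input only: zero
        assert not e2d.flags["chr1"][1, 2]

    def test_alpha_arithmetic_and_linearity(self):
        ip = [("chr1", 10, 100)] * 4
        inp = [("chr1", 20, 100)] * 8
        half = simple_e2d(ip, inp, alpha=0.5)
        assert half.values["chr1"][0, 2] == pytest.approx(0.25)
        one = simple_e2d(ip, inp, alpha=1.0)
        two = simple_e2d(ip, inp, alpha=2.0)
        for chrom in one.values:
            assert np.allclose(2 * one.values[chrom], two.values[chrom])

    def test_mismatched_binning_rejected(self):
        a = bin2d(make_fragments([("chr1", 0, 100)]), 1000, 50)
        b = bin2d(make_fragments([("chr1", 0, 100)]), 2000, 50)
        with pytest.raises(GeometryError):
            efficiency2d(a, b, 1.0)

    def test_sequencer_constant_cancellation(self):
        """Duplicating every record a common number of times leaves e(x)
        unchanged -- per-sequencer proportionality constants cancel."""
        rng = np.random.default_rng(3)
        ip = [("chr1", int(s), int(l)) for s, l in zip(
            rng.integers(0, 20_000, 200), rng.integers(60, 300, 200))]
        inp = [("chr1", int(s), int(l)) for s, l in zip(
            rng.integers(0, 20_000, 300), rng.integers(60, 300, 300))]
        base = project1d(simple_e2d(ip, inp))
        dup = project1d(simple_e2d(ip * 3, inp * 3))
        assert np.allclose(base.values["chr1"], dup.values["chr1"])


class TestProject1d:
    def manual_e2d(self, values, weights):
        values = np.asarray(values, dtype=float)[None, :]
        weights = np.asarray(weights, dtype=np.int64)[None, :]
        return Efficiency2D(interval_width=1000, length_bin_width=50,
                            values={"chr1": values},
                            ip_counts={"chr1": (values > 0).astype(np.int64)},
                            input_counts={"chr1": weights},
                            flags={"chr1": np.zeros_like(values, dtype=bool)})

    def test_constant_value_independent_of_weights(self):
        track = project1d(self.manual_e2d([0.7, 0.7, 0.7], [5, 1, 9]))
        assert track.values["chr1"][0] == pytest.approx(0.7)

    def test_single_occupied_length_bin(self):
        track = project1d(self.manual_e2d([0.0, 0.4, 0.0], [0, 6, 0]))
        assert track.values["chr1"][0] == pytest.approx(0.4)

    def test_weighted_mean_hand_example(self):
        track = project1d(self.manual_e2d([0.2, 0.6], [3, 1]))
        assert track.values["chr1"][0] == pytest.approx(0.3)

    def test_per_fragment_is_per_base_times_mean_length(self):
        e2d = self.manual_e2d([0.2, 0.6], [3, 1])
        per_base = project1d(e2d)
        per_frag = per_base.per_fragment(mean_length=180.0)
        nz = per_base.values["chr1"] > 0
        assert np.allclose(per_frag.values["chr1"][nz],
                           per_base.values["chr1"][nz] * 180.0)
        assert per_frag.unit == "per-fragment"


class TestStabilizeWidth:
    def test_deep_uniform_coverage_accepts_smallest_width(self):
        rng = np.random.default_rng(5)
        n = 40_000
        ip = [("chr1", int(s), int(l)) for s, l in zip(
            rng.integers(0, 100_000, n), rng.integers(100, 200, n))]
        inp = [("chr1", int(s), int(l)) for s, l in zip(
            rng.integers(0, 100_000, n), rng.integers(100, 200, n))]
        res = stabilize_width(make_fragments(ip), make_fragments(inp), 1.0,
                              widths=[1000, 2000, 5000], criterion=0.1)
        assert res.converged and res.width == 1000

    def test_sparse_data_zero_flags_shrink_with_width(self):
        rng = np.random.default_rng(9)
        n = 150
        ip = [("chr1", int(s), int(l)) for s, l in zip(
            rng.integers(0, 500_000, n), rng.integers(100, 200, n))]
        inp = [("chr1", int(s), int(l)) for s, l in zip(
            rng.integers(0, 500_000, n), rng.integers(100, 200, n))]
        res = stabilize_width(make_fragments(ip), make_fragments(inp), 1.0,
                              widths=[1000, 4000, 16000, 64000, 256000],
                              criterion=1e-9)
        frac = res.diagnostics["zero_flag_fraction"].to_numpy()
        assert np.all(np.diff(frac) <= 0)

    def test_unconverged_returns_largest_width_with_flag(self):
        rng = np.random.default_rng(13)
        n = 5000
        ip = [("chr1", int(s), 150) for s in rng.integers(0, 100_000, n)]
        inp = [("chr1", int(s), 150) for s in rng.integers(0, 100_000, n)]
        res = stabilize_width(make_fragments(ip), make_fragments(inp), 1.0,
                              widths=[1000, 2000], criterion=1e-12)
        assert not res.converged and res.width == 2000

    def test_widths_must_increase(self):
        frags = make_fragments([("chr1", 0, 100)])
        with pytest.raises(ValueError):
            stabilize_width(frags, frags, 1.0, widths=[2000, 1000])


class TestDifferential:
    def track(self, values):
        return EfficiencyTrack(interval_width=1000,
                               values={"chr1": np.asarray(values, float)})

    def test_identical_tracks_are_unity(self):
        t = self.track([0.5, 0.2, 0.9])
        vals = differential(t, t).values["chr1"]
        assert np.allclose(vals, 1.0)

    def test_zero_control_is_missing_not_zero_or_inf(self):
        d = differential(self.track([0.5, 0.5]), self.track([0.25, 0.0]))
        vals = d.values["chr1"]
        assert vals[0] == pytest.approx(2.0)
        assert np.isnan(vals[1])

    def test_geometry_mismatch(self):
        other = EfficiencyTrack(interval_width=500,
                                values={"chr1": np.array([1.0])})
        with pytest.raises(GeometryError):
            differential(self.track([1.0]), other)


class TestBedGraph:
    def test_single_bin_line(self, tmp_path):
        track = EfficiencyTrack(interval_width=1000,
                                values={"chr1": np.array([0.25])})
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, path)
        assert path.read_text() == "chr1\t0\t1000\t0.25\n"

    def test_empty_track_empty_file(self, tmp_path):
        path = tmp_path / "e.bedgraph"
        write_bedgraph(EfficiencyTrack(interval_width=1000), path)
        assert path.read_text() == ""

    def test_round_trip_idempotent_on_random_track(self, tmp_path):
        rng = np.random.default_rng(17)
        vals = np.round(rng.random(50), 4)
        vals[rng.random(50) < 0.3] = 0.0
        track = EfficiencyTrack(interval_width=2000,
                                values={"chr1": vals, "chr2": vals[::-1].copy()})
        p1, p2 = tmp_path / "a.bedgraph", tmp_path / "b.bedgraph"
        write_bedgraph(track, p1)
        write_bedgraph(read_bedgraph(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_merged_runs_cover_same_values(self, tmp_path):
        track = EfficiencyTrack(
            interval_width=100,
            values={"chr1": np.array([0.5, 0.5, 0.0, 0.25, 0.25, 0.25])})
        path = tmp_path / "m.bedgraph"
        write_bedgraph(track, path, merge=True)
        assert path.read_text() == ("chr1\t0\t200\t0.5\n"
                                    "chr1\t300\t600\t0.25\n")
        back = read_bedgraph(path, interval_width=100)
        assert np.allclose(back.values["chr1"], track.values["chr1"])


def test_end_to_end_profile_uses_ip_mean_length(generated_pair):
    exp = generated_pair[10_000]
    track = efficiency_profile(exp.ip, exp.input, exp.ledger.alpha_true,
                               10_000, 10)
    assert track.mean_length == pytest.approx(exp.ip.mean_length)
    pf = track.per_fragment()
    chrom = next(iter(track.values))
    nz = track.values[chrom] > 0
    ratio = pf.values[chrom][nz] / track.values[chrom][nz]
    assert np.allclose(ratio, exp.ip.mean_length)
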
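import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modcalc.mlc_sequence import (ControlPoint, DynamicSequence, LeafGeometry,
                                  MLCParseError, apply_dosimetric_gap,
                                  closed_field_sequence,
                                  generate_sweeping_checker,
                                  generate_sweeping_window,
                                  open_counterpart, open_field_sequence,
                                  parse_arc_table, parse_mlc_file,
                                  resample_time, write_arc_table,
                                  write_mlc_file)

GEOM = LeafGeometry.millennium120()


def _static(tips_a, tips_b, jaws=(-50, 50, -50, 50), mu=100.0, kind="dynamic"):
    cp0 = ControlPoint(0.0, tips_a, tips_b)
    cp1 = ControlPoint(1.0, tips_a, tips_b)
    return DynamicSequence(GEOM, (cp0, cp1), jaws, 0.0, mu, kind)


class TestGeometry:
    def test_millennium_layout(self):
        assert GEOM.n_pairs == 60
        widths = sorted(set(np.round(GEOM.widths, 6)))
        assert widths == [5.0, 10.0]
        assert GEOM.boundaries[0] == -200.0 and GEOM.boundaries[-1] == 200.0

    def test_rejects_more_than_two_widths(self):
        with pytest.raises(ValueError, match="two distinct"):
            LeafGeometry((0.0, 5.0, 12.0, 20.0, 21.0))

    def test_rejects_unsorted_boundaries(self):
        with pytest.raises(ValueError, match="increasing"):
            LeafGeometry((0.0, 10.0, 5.0))

    def test_pair_lookup(self):
        assert GEOM.pair_of(np.array([-210.0]))[0] == -1
        assert GEOM.pair_of(np.array([0.1]))[0] == GEOM.pair_of(np.array([4.9]))[0]


class TestValidation:
    def test_negative_aperture_rejected(self):
        with pytest.raises(ValueError, match="negative aperture"):
            ControlPoint(0.0, (5.0,) * 60, (-5.0,) * 60)

    def test_empty_jaws_rejected(self):
        with pytest.raises(ValueError, match="rectangle"):
            _static((-10.0,) * 60, (10.0,) * 60, jaws=(50, -50, -50, 50))

    def test_two_points_minimum(self):
        cp = ControlPoint(0.0, (-10.0,) * 60, (10.0,) * 60)
        with pytest.raises(ValueError, match="two control points"):
            DynamicSequence(GEOM, (cp,), (-50, 50, -50, 50))


class TestFileRoundTrip:
    def test_open_field_minimal(self, tmp_path):
        seq = open_field_sequence(10.0, 1.0)
        path = tmp_path / "open.mlc"
        write_mlc_file(seq, path)
        back = parse_mlc_file(path, GEOM)
        assert len(back.points) == 2
        assert back.points[0].index == 0.0 and back.points[1].index == 1.0
        assert back.approx_equal(seq)

    @pytest.mark.parametrize("maker", [
        lambda: generate_sweeping_window(1.0, 10.0, 400.0),
        lambda: generate_sweeping_checker(4.0, 10.0, 400.0),
        lambda: closed_field_sequence(10.0, 400.0),
    ])
    def test_generated_sequences_round_trip(self, tmp_path, maker):
        seq = maker()
        path = tmp_path / "field.mlc"
        write_mlc_file(seq, path)
        assert parse_mlc_file(path, GEOM).approx_equal(seq)

    def test_write_is_bit_stable(self, tmp_path):
        seq = generate_sweeping_window(1.0, 10.0, 400.0)
        write_mlc_file(seq, tmp_path / "a.mlc")
        write_mlc_file(seq, tmp_path / "b.mlc")
        assert (tmp_path / "a.mlc").read_bytes() == (tmp_path / "b.mlc").read_bytes()

    def test_gantry_column_round_trips_in_text_dialect(self, tmp_path):
        cps = tuple(ControlPoint(i / 2.0, (-20.0,) * 60, (20.0,) * 60,
                                 gantry_deg=180.0 - 30.0 * i)
                    for i in range(3))
        seq = DynamicSequence(GEOM, cps, (-50, 50, -50, 50), 0.0, 200.0, "arc")
        path = tmp_path / "arc.mlc"
        write_mlc_file(seq, path)
        back = parse_mlc_file(path, GEOM)
        assert [p.gantry_deg for p in back.points] == [180.0, 150.0, 120.0]

    def test_arc_table_round_trip(self, tmp_path):
        cps = tuple(ControlPoint(i, (-30.0,) * 60, (10.0,) * 60, gantry_deg=g)
                    for i, g in ((0.0, 179.0), (0.5, 90.0), (1.0, 0.0)))
        seq = DynamicSequence(GEOM, cps, (-40, 40, -55, 55), 10.0, 300.0, "arc")
        path = tmp_path / "arc.csv"
        write_arc_table(seq, path)
        back = parse_arc_table(path, GEOM)
        assert back.approx_equal(seq)
        assert back.delivery_kind == "arc"

    def test_non_monotonic_index_names_control_point(self, tmp_path):
        cps = tuple(ControlPoint(i, (-10.0,) * 60, (10.0,) * 60)
                    for i in (0.0, 0.6, 1.0))
        seq = DynamicSequence(GEOM, cps, (-50, 50, -50, 50))
        path = tmp_path / "bad.mlc"
        write_mlc_file(seq, path)
        text = path.read_text().replace("Index = 1.0000", "Index = 0.4000")
        path.write_text(text)
        with pytest.raises(MLCParseError, match="control point 3"):
            parse_mlc_file(path, GEOM)

    def test_wrong_leaf_count_rejected(self, tmp_path):
        seq = open_field_sequence(10.0, 1.0)
        path = tmp_path / "short.mlc"
        write_mlc_file(seq, path)
        lines = [ln for ln in path.read_text().splitlines()
                 if not ln.startswith("Leaf  60B")]
        path.write_text("\n".join(lines))
        with pytest.raises(MLCParseError, match="control point 1"):
            parse_mlc_file(path, GEOM)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "junk.mlc"
        path.write_text("not an mlc file\n")
        with pytest.raises(MLCParseError, match="header"):
            parse_mlc_file(path, GEOM)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(2, 5), st.integers(0, 2 ** 31 - 1))
    def test_random_sequences_round_trip(self, tmp_path_factory, n_cp, seed):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.uniform(0, 1, n_cp))
        idx[0], idx[-1] = 0.0, 1.0
        points = []
        for i in idx:
            a = np.round(rng.uniform(-100, 50, 60), 1)
            b = np.round(a + rng.uniform(0.1, 60, 60), 1)
            points.append(ControlPoint(round(i, 4), tuple(a), tuple(b)))
        seq = DynamicSequence(GEOM, tuple(points), (-50, 50, -50, 50),
                              0.0, 250.0)
        path = tmp_path_factory.mktemp("rt") / "seq.mlc"
        write_mlc_file(seq, path)
        assert parse_mlc_file(path, GEOM).approx_equal(seq, tol_mm=0.051)


class TestResampleTime:
    def test_static_field_all_samples_identical(self):
        seq = _static((-10.0,) * 60, (10.0,) * 60)
        s = resample_time(seq, 600)
        assert s.n_intervals == 600
        assert np.all(s.tips_a == -10.0) and np.all(s.tips_b == 10.0)
        assert np.allclose(s.weights, 1.0 / 600)
        assert s.weights.sum() == 1.0

    def test_sweep_midpoint_interpolation(self):
        cps = (ControlPoint(0.0, (-50.0,) * 60, (-50.0,) * 60),
               ControlPoint(1.0, (50.0,) * 60, (50.0,) * 60))
        seq = DynamicSequence(GEOM, cps, (-50, 50, -50, 50))
        s = resample_time(seq, 4)
        assert np.allclose(s.tips_a[:, 0], [-37.5, -12.5, 12.5, 37.5])

    def test_arc_increments_follow_meterset_table(self):
        cps = tuple(ControlPoint(i, (-10.0,) * 60, (10.0,) * 60, gantry_deg=g)
                    for i, g in ((0.0, 0.0), (0.5, 30.0), (0.8, 60.0), (1.0, 90.0)))
        seq = DynamicSequence(GEOM, cps, (-50, 50, -50, 50),
                              delivery_kind="arc")
        s = resample_time(seq, 3)
        assert np.allclose(s.weights, [0.5, 0.3, 0.2])
        assert s.weights.sum() == 1.0
        assert s.gantry_deg is not None
        assert np.all(np.diff(s.gantry_deg) > 0)

    def test_step_and_shoot_holds_segments(self):
        cps = (ControlPoint(0.0, (-20.0,) * 60, (0.0,) * 60),
               ControlPoint(0.5, (-20.0,) * 60, (0.0,) * 60),
               ControlPoint(0.5, (0.0,) * 60, (20.0,) * 60),
               ControlPoint(1.0, (0.0,) * 60, (20.0,) * 60))
        seq = DynamicSequence(GEOM, cps, (-50, 50, -50, 50),
                              delivery_kind="step_and_shoot")
        s = resample_time(seq, 10)
        assert np.all(s.tips_b[:5] == 0.0) and np.all(s.tips_b[5:] == 20.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(1, 977))
    def test_weights_always_partition_unity(self, n):
        seq = generate_sweeping_window(2.0, 10.0, 100.0)
        assert abs(resample_time(seq, n).weights.sum() - 1.0) < 1e-12

    def test_rejects_zero_intervals(self):
        with pytest.raises(ValueError):
            resample_time(open_field_sequence(10.0, 1.0), 0)


class TestDosimetricGap:
    def test_gap_widens_by_dlg(self):
        seq = _static((-5.0,) * 60, (5.0,) * 60)
        s = apply_dosimetric_gap(resample_time(seq, 3), 1.9)
        gaps = s.tips_b - s.tips_a
        assert np.allclose(gaps, 11.9)

    def test_zero_dlg_is_identity(self):
        seq = generate_sweeping_window(1.0, 10.0, 100.0)
        s0 = resample_time(seq, 7)
        s1 = apply_dosimetric_gap(s0, 0.0)
        assert np.array_equal(s0.tips_a, s1.tips_a)
        assert np.array_equal(s0.tips_b, s1.tips_b)

    def test_closed_pairs_exempt(self):
        seq = closed_field_sequence(10.0, 100.0)
        s = apply_dosimetric_gap(resample_time(seq, 2), 1.9)
        assert np.all(s.tips_b - s.tips_a == 0.0)

    def test_exemption_can_be_disabled(self):
        seq = closed_field_sequence(10.0, 100.0)
        s = apply_dosimetric_gap(resample_time(seq, 2), 1.9,
                                 exempt_closed=False)
        assert np.allclose(s.tips_b - s.tips_a, 1.9)

    def test_ordering_preserved(self):
        seq = generate_sweeping_checker(4.0, 10.0, 100.0)
        s = apply_dosimetric_gap(resample_time(seq, 11), 1.9)
        assert np.all(s.tips_b >= s.tips_a)


class TestGenerators:
    def test_window_moves_in_unison(self):
        seq = generate_sweeping_window(1.0, 10.0, 400.0)
        for p in seq.points:
            assert len(set(p.bank_a)) == 1 and len(set(p.bank_b)) == 1
            assert np.allclose(np.array(p.bank_b) - np.array(p.bank_a), 10.0)
        assert seq.jaws == (-50.0, 50.0, -50.0, 50.0)

    def test_checker_staggers_alternating_pairs(self):
        seq = generate_sweeping_checker(4.0, 10.0, 400.0)
        a = np.array(seq.points[0].bank_a)
        assert np.allclose(a[1::2] - a[0::2], 40.0)
        b = np.array(seq.points[0].bank_b)
        assert np.allclose(b - a, 40.0)

    def test_gap_equal_to_field_degenerates_to_open(self):
        seq = generate_sweeping_window(10.0, 10.0, 100.0)
        for p in seq.points:
            assert max(p.bank_a) < seq.jaws[0]
            assert min(p.bank_b) > seq.jaws[1]

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            generate_sweeping_window(12.0, 10.0, 100.0)
        with pytest.raises(ValueError):
            generate_sweeping_checker(-1.0, 10.0, 100.0)

    def test_open_counterpart_keeps_field_parameters(self):
        seq = generate_sweeping_checker(4.0, 10.0, 400.0)
        op = open_counterpart(seq)
        assert op.jaws == seq.jaws and op.total_mu == seq.total_mu
        assert max(p for cp in op.points for p in cp.bank_a) < seq.jaws[0]
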
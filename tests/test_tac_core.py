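"""Frame schedules, TAC extraction, decay/SUV corrections, and CSV/NIfTI I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spectkin as sk
from spectkin.errors import ParseError, UnitsError, ValidationError


class TestFrameSchedule:
    def test_two_phase_protocol(self, protocol_schedule):
        """8 x 2.5 min + 8 x 20 min gives 16 contiguous frames over 180 min."""
        s = protocol_schedule
        assert s.n_frames == 16
        assert s.total_duration_min == pytest.approx(180.0)
        assert s.start_min[0] == 0.0
        assert np.allclose(s.start_min[1:], s.end_min[:-1])

    def test_single_frame(self):
        s = sk.build_frame_schedule([(1, 5.0)])
        assert s.n_frames == 1
        assert s.start_min[0] == 0.0 and s.end_min[0] == 5.0

    def test_mixed_phases_cumulative_starts(self):
        s = sk.build_frame_schedule([(3, 1.0), (2, 2.0)])
        assert np.allclose(s.start_min, [0, 1, 2, 3, 5])
        assert s.total_duration_min == pytest.approx(7.0)

    @pytest.mark.parametrize("phases", [[(0, 2.5)], [(3, 0.0)], [(2, -1.0)], []])
    def test_invalid_phases_rejected(self, phases):
        with pytest.raises(ValidationError):
            sk.build_frame_schedule(phases)

    def test_overlapping_frames_rejected(self):
        with pytest.raises(ValidationError):
            sk.FrameSchedule(np.array([0.0, 1.0]), np.array([2.0, 1.0]))

    @given(
        st.lists(
            st.tuples(st.integers(1, 5), st.floats(0.1, 30.0)),
            min_size=1,
            max_size=4,
        )
    )
    def test_phase_builder_invariants(self, phases):
        """Any positive phase spec yields a valid, contiguous schedule."""
        s = sk.build_frame_schedule(phases)
        assert np.all(s.duration_min > 0)
        assert np.all(np.diff(s.start_min) > 0)
        assert np.all(s.start_min[1:] >= s.end_min[:-1] - 1e-9)
        total = sum(n * d for n, d in phases)
        assert s.total_duration_min == pytest.approx(total)


class TestExtractTac:
    def _image(self, data, schedule):
        return sk.DynamicImage(data, (0.5, 0.5, 0.5), schedule)

    def test_single_voxel_identity(self):
        sched = sk.build_frame_schedule([(4, 1.0)])
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 10, (3, 3, 3, 4))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 2, 0] = True
        tac = sk.extract_tac(self._image(data, sched), sk.VOIMask(mask))
        assert np.array_equal(tac.values, data[1, 2, 0])

    def test_constant_region(self):
        sched = sk.build_frame_schedule([(5, 2.0)])
        data = np.zeros((4, 4, 4, 5))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2, :2, :2] = True
        data[mask] = 7.0
        tac = sk.extract_tac(self._image(data, sched), sk.VOIMask(mask))
        assert np.all(tac.values == 7.0)

    def test_matches_brute_force_voxel_mean(self):
        """VOI mean equals an explicit per-voxel loop on a random phantom."""
        sched = sk.build_frame_schedule([(6, 2.5)])
        rng = np.random.default_rng(7)
        data = rng.uniform(0, 50, (6, 5, 4, 6))
        mask = rng.uniform(size=(6, 5, 4)) < 0.3
        mask[0, 0, 0] = True  # ensure non-empty
        tac = sk.extract_tac(self._image(data, sched), sk.VOIMask(mask))
        expected = np.zeros(6)
        n = 0
        for i in range(6):
            for j in range(5):
                for k in range(4):
                    if mask[i, j, k]:
                        expected += data[i, j, k]
                        n += 1
        assert np.allclose(tac.values, expected / n, rtol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            sk.VOIMask(np.zeros((3, 3, 3), dtype=bool))

    def test_grid_mismatch_rejected(self):
        sched = sk.build_frame_schedule([(2, 1.0)])
        img = self._image(np.zeros((3, 3, 3, 2)), sched)
        with pytest.raises(ValidationError):
            sk.extract_tac(img, sk.VOIMask(np.ones((4, 4, 4), dtype=bool)))


class TestDecayCorrection:
    def _tac(self, times, values):
        return sk.TimeActivityCurve(values, sample_times_min=np.asarray(times, float))

    def test_value_at_reference_unchanged(self):
        tac = self._tac([0.0, 60.0], [5.0, 5.0])
        out = sk.decay_correct(tac, reference_min=0.0)
        assert out.values[0] == pytest.approx(5.0, abs=0)

    def test_factor_two_at_one_half_life(self):
        t_half_min = 6.0058 * 60.0
        tac = self._tac([0.0, t_half_min], [1.0, 1.0])
        out = sk.decay_correct(tac, half_life_hours=6.0058)
        assert out.values[1] == pytest.approx(2.0, rel=1e-15)

    def test_factor_at_180_min(self):
        tac = self._tac([0.0, 180.0], [1.0, 1.0])
        out = sk.decay_correct(tac, half_life_hours=6.0058)
        assert out.values[1] == pytest.approx(2.0 ** (180.0 / 360.348), rel=1e-12)

    def test_double_correction_rejected(self):
        tac = self._tac([0.0, 10.0], [1.0, 1.0])
        once = sk.decay_correct(tac)
        with pytest.raises(ValidationError):
            sk.decay_correct(once)

    @given(st.floats(0.5, 12.0), st.integers(0, 2**31 - 1))
    def test_round_trip_machine_precision(self, half_life, seed):
        """Correct-then-uncorrect restores the curve to machine precision."""
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 200, 8))
        times += np.arange(8) * 1e-3  # guarantee strictly increasing
        vals = rng.uniform(0.1, 100, 8)
        tac = self._tac(times, vals)
        back = sk.decay_uncorrect(
            sk.decay_correct(tac, half_life_hours=half_life), half_life_hours=half_life
        )
        assert np.allclose(back.values, vals, rtol=1e-14)
        assert not back.decay_corrected

    def test_framed_tac_uses_mid_time(self, protocol_schedule):
        """Frame decay factors are evaluated at mid-frame, not frame start."""
        tac = sk.TimeActivityCurve(np.ones(16), schedule=protocol_schedule)
        out = sk.decay_correct(tac, half_life_hours=6.0058)
        expected = 2.0 ** (protocol_schedule.mid_min / (6.0058 * 60.0))
        assert np.allclose(out.values, expected, rtol=1e-14)


class TestSuv:
    def test_uniform_distribution_gives_unity(self):
        dose = sk.DoseRecord(dose_mbq=500.0, body_weight_g=250.0)
        c = 500.0 * 1e3 / 250.0  # kBq/ml at perfectly uniform distribution
        tac = sk.TimeActivityCurve(np.full(3, c), sample_times_min=np.array([1.0, 2.0, 3.0]))
        suv = sk.compute_suv(tac, dose)
        assert np.allclose(suv.values, 1.0, rtol=1e-14)
        assert suv.units == "SUV"

    def test_hand_computed_scalar(self):
        # dose 521.5 MBq into a 263 g subject, C = 3.9658 kBq/ml:
        # SUV = 3.9658 * 263 / 521500 = 2.000010...e-3 (scalar arithmetic)
        dose = sk.DoseRecord(dose_mbq=521.5, body_weight_g=263.0)
        tac = sk.TimeActivityCurve(np.array([3.9658]), sample_times_min=np.array([60.0]))
        suv = sk.compute_suv(tac, dose)
        assert suv.values[0] == pytest.approx(0.00200001, rel=1e-5)

    def test_halving_dose_doubles_suv(self):
        tac = sk.TimeActivityCurve(np.array([10.0]), sample_times_min=np.array([5.0]))
        full = sk.compute_suv(tac, sk.DoseRecord(400.0, 200.0))
        half = sk.compute_suv(tac, sk.DoseRecord(200.0, 200.0))
        assert np.allclose(half.values, 2 * full.values, rtol=1e-14)

    def test_consistent_unit_rescaling_invariance(self):
        """Scaling C and dose by a common factor leaves SUV unchanged."""
        tac = sk.TimeActivityCurve(np.array([4.2, 8.1]), sample_times_min=np.array([1.0, 2.0]))
        base = sk.compute_suv(tac, sk.DoseRecord(500.0, 250.0))
        scaled = sk.compute_suv(tac.with_values(tac.values * 37.0), sk.DoseRecord(500.0 * 37.0, 250.0))
        assert np.allclose(base.values, scaled.values, rtol=1e-14)

    def test_unit_mismatch_rejected(self):
        tac = sk.TimeActivityCurve(
            np.array([1.0]), sample_times_min=np.array([1.0]), units="SUV"
        )
        with pytest.raises(UnitsError):
            sk.compute_suv(tac, sk.DoseRecord(100.0, 100.0))


class TestTacTableIO:
    def test_framed_round_trip(self, tmp_path, protocol_schedule):
        rng = np.random.default_rng(3)
        tac = sk.TimeActivityCurve(
            rng.uniform(0, 30, 16),
            schedule=protocol_schedule,
            decay_corrected=True,
            decay_reference_min=0.0,
        )
        path = tmp_path / "tac.csv"
        sk.write_tac_table(tac, path)
        back = sk.read_tac_table(path)
        assert np.allclose(back.values, tac.values, rtol=1e-12)
        assert np.allclose(back.schedule.start_min, tac.schedule.start_min)
        assert np.allclose(back.schedule.duration_min, tac.schedule.duration_min)
        assert back.decay_corrected and back.decay_reference_min == 0.0

    def test_discrete_round_trip(self, tmp_path):
        tac = sk.TimeActivityCurve(
            np.array([1.5, 2.5]), sample_times_min=np.array([2.5, 5.0])
        )
        path = tmp_path / "blood.csv"
        sk.write_tac_table(tac, path)
        back = sk.read_tac_table(path)
        assert np.allclose(back.values, tac.values)
        assert np.allclose(back.sample_times_min, tac.sample_times_min)

    def test_schedule_reconstructed_exactly(self, tmp_path, protocol_schedule):
        """A 16-row file reproduces the constructed two-phase schedule."""
        tac = sk.TimeActivityCurve(np.ones(16), schedule=protocol_schedule)
        path = tmp_path / "t.csv"
        sk.write_tac_table(tac, path)
        back = sk.read_tac_table(path)
        assert np.array_equal(back.schedule.start_min, protocol_schedule.start_min)
        assert np.array_equal(back.schedule.duration_min, protocol_schedule.duration_min)

    def test_negative_duration_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time_start_min,duration_min,value_kBq_per_ml\n0.0,2.5,1.0\n2.5,-1.0,2.0\n"
        )
        with pytest.raises(ParseError) as err:
            sk.read_tac_table(path)
        assert err.value.line == 3

    def test_non_numeric_cell_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_min,value\n1.0,2.0\n2.0,oops\n")
        with pytest.raises(ParseError) as err:
            sk.read_tac_table(path)
        assert err.value.line == 3

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_start_min,value\n0.0,1.0\n")
        with pytest.raises(ParseError):
            sk.read_tac_table(path)


class TestNiftiIO:
    def test_dynamic_image_round_trip(self, tmp_path):
        sched = sk.build_frame_schedule([(3, 2.5)])
        rng = np.random.default_rng(5)
        img = sk.DynamicImage(
            rng.uniform(0, 10, (6, 6, 6, 3)), (0.5, 0.5, 0.5), sched, decay_corrected=True
        )
        path = tmp_path / "dyn.nii.gz"
        sk.save_dynamic_image(img, path)
        back = sk.load_dynamic_image(path)
        assert np.allclose(back.data, img.data, rtol=1e-6)  # float32 on disk
        assert np.allclose(back.schedule.start_min, sched.start_min)
        assert back.voxel_size_mm == pytest.approx((0.5, 0.5, 0.5))
        assert back.decay_corrected

    def test_mask_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        m = rng.uniform(size=(5, 5, 5)) < 0.4
        m[0, 0, 0] = True
        path = tmp_path / "mask.nii.gz"
        sk.save_voi_mask(sk.VOIMask(m, label="sheet"), path)
        back = sk.load_voi_mask(path, label="sheet")
        assert np.array_equal(back.mask, m)
        assert back.label == "sheet"
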
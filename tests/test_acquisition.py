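"""Acquisition I/O, down-sampling, output correction, profile extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stepwedge as sw
from stepwedge.acquisition import beam_on_mask
from stepwedge.errors import (
    AcquisitionFormatError,
    MonitorSignalError,
    SegmentTooShortError,
)


class TestFileDialect:
    def test_round_trip_is_lossless(self, tmp_path, small_acquisition):
        path = tmp_path / "acq.csv"
        sw.write_acquisition(small_acquisition, path)
        back = sw.read_acquisition(path)
        np.testing.assert_array_equal(back.signal, small_acquisition.signal)
        np.testing.assert_array_equal(back.monitor, small_acquisition.monitor)
        assert back.dt_s == small_acquisition.dt_s
        assert back.meta == small_acquisition.meta

    def test_wrong_channel_count_rejected(self, tmp_path):
        path = tmp_path / "acq.csv"
        header = "projection,monitor," + ",".join(f"ch{c:04d}" for c in range(639))
        row = "0,1.0," + ",".join("0.5" for _ in range(639))
        path.write_text(header + "\n" + row + "\n")
        path.with_name("acq.meta.json").write_text('{"dt_s": 0.033, "meta": {}}')
        with pytest.raises(AcquisitionFormatError, match="[Cc]hannel count"):
            sw.read_acquisition(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "acq.csv"
        path.write_text("")
        with pytest.raises(AcquisitionFormatError):
            sw.read_acquisition(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(AcquisitionFormatError):
            sw.read_acquisition(tmp_path / "nothing.csv")

    def test_negative_signal_rejected(self):
        with pytest.raises(AcquisitionFormatError, match="negative"):
            sw.DetectorAcquisition(
                signal=np.array([[1.0, -0.1], [1.0, 1.0]]), monitor=np.ones(2)
            )

    def test_monitor_length_mismatch_rejected(self):
        with pytest.raises(AcquisitionFormatError, match="monitor"):
            sw.DetectorAcquisition(signal=np.ones((5, 4)), monitor=np.ones(4))


class TestDownsample:
    def test_constant_input_stays_constant(self):
        acq = sw.DetectorAcquisition(
            signal=np.full((9000, 4), 3.0), monitor=np.ones(9000), dt_s=1.0 / 300.0
        )
        out = sw.downsample_10to1(acq)
        assert out.n_projections == 900
        assert out.dt_s == pytest.approx(1.0 / 30.0)
        np.testing.assert_allclose(out.signal, 3.0)

    def test_alternating_rows_average_to_one(self):
        sig = np.tile(np.array([[0.0], [2.0]]), (50, 1))
        acq = sw.DetectorAcquisition(signal=sig, monitor=np.ones(100), dt_s=0.01)
        out = sw.downsample_10to1(acq)
        np.testing.assert_allclose(out.signal, 1.0)
        np.testing.assert_allclose(out.monitor, 1.0)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_matches_block_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sig = rng.uniform(0, 5, size=(40, 3))
        mon = rng.uniform(0.5, 2, size=40)
        acq = sw.DetectorAcquisition(signal=sig, monitor=mon, dt_s=0.1)
        out = sw.downsample_10to1(acq)
        # independent oracle: explicit loop over 10-blocks
        expect = np.array([sig[10 * i : 10 * (i + 1)].mean(axis=0) for i in range(4)])
        np.testing.assert_allclose(out.signal, expect, atol=1e-12)
        np.testing.assert_allclose(
            out.monitor, [mon[10 * i : 10 * (i + 1)].mean() for i in range(4)], atol=1e-12
        )

    def test_preserves_signal_time_integral(self):
        rng = np.random.default_rng(3)
        acq = sw.DetectorAcquisition(
            signal=rng.uniform(0, 1, (200, 2)), monitor=np.ones(200), dt_s=0.01
        )
        out = sw.downsample_10to1(acq)
        assert out.signal.sum() * out.dt_s == pytest.approx(
            acq.signal.sum() * acq.dt_s, rel=1e-9
        )

    def test_remainder_dropped_with_warning(self):
        acq = sw.DetectorAcquisition(
            signal=np.ones((25, 2)), monitor=np.ones(25), dt_s=0.01
        )
        with pytest.warns(UserWarning, match="trailing"):
            out = sw.downsample_10to1(acq)
        assert out.n_projections == 2

    def test_too_few_rows_rejected(self):
        acq = sw.DetectorAcquisition(signal=np.ones((5, 2)), monitor=np.ones(5))
        with pytest.raises(AcquisitionFormatError):
            sw.downsample_10to1(acq)


class TestOutputCorrection:
    def test_constant_monitor_leaves_signal_unchanged(self):
        rng = np.random.default_rng(0)
        sig = rng.uniform(0.5, 1.5, (200, 3))
        acq = sw.DetectorAcquisition(signal=sig, monitor=np.full(200, 2.0))
        out = sw.output_correct(acq)
        np.testing.assert_allclose(out.signal, sig, rtol=1e-12)

    def test_signal_proportional_to_monitor_becomes_constant(self):
        rng = np.random.default_rng(1)
        mon = rng.uniform(0.8, 1.2, 300)
        acq = sw.DetectorAcquisition(
            signal=np.repeat(mon[:, None], 4, axis=1), monitor=mon
        )
        out = sw.output_correct(acq)
        np.testing.assert_allclose(out.signal, mon.mean(), rtol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        acq = sw.DetectorAcquisition(
            signal=rng.uniform(0, 2, (150, 3)), monitor=rng.uniform(0.9, 1.1, 150)
        )
        once = sw.output_correct(acq)
        twice = sw.output_correct(once)
        np.testing.assert_allclose(twice.signal, once.signal, atol=1e-12)

    def test_removes_simulated_output_ripple(self):
        # 2% sinusoidal ripple, no detector noise: after correction the
        # residual ripple on the air segment is below 0.1% of the mean.
        scn = sw.SimulationScenario(
            noise_rel=0.0, output_ripple=(0.02, 10.0), seed=5
        )
        acq, _ = sw.simulate_acquisition(scn)
        raw = acq.signal[:900, 320]
        assert raw.std() / raw.mean() > 0.01  # ripple present before correction
        corr = sw.output_correct(acq).signal[:900, 320]
        assert corr.std() / corr.mean() < 0.001

    def test_nonpositive_monitor_in_beam_rejected(self):
        mon = np.ones(200)
        mon[100] = 0.0
        acq = sw.DetectorAcquisition(signal=np.ones((200, 2)), monitor=mon)
        with pytest.raises(MonitorSignalError, match="100"):
            sw.output_correct(acq)

    def test_beam_off_tails_zeroed(self):
        mon = np.concatenate([np.full(20, 1e-3), np.ones(200), np.full(20, 1e-3)])
        acq = sw.DetectorAcquisition(signal=np.ones((240, 2)), monitor=mon)
        out = sw.output_correct(acq)
        assert beam_on_mask(mon).sum() == 200
        np.testing.assert_allclose(out.signal[:20], 0.0)
        np.testing.assert_allclose(out.signal[-20:], 0.0)
        np.testing.assert_allclose(out.signal[20:220], 1.0, rtol=1e-12)


class TestProfileExtraction:
    def test_time_profile_matches_generating_channel(self, noiseless_sim):
        acq, truth = noiseless_sim
        prof = sw.extract_time_profile(acq, 320)
        assert prof.channel_index == 320
        np.testing.assert_array_equal(prof.values, acq.signal[:, 320])

    def test_default_channel_is_center(self, noiseless_sim):
        acq, _ = noiseless_sim
        assert sw.extract_time_profile(acq).channel_index == 320

    def test_out_of_range_channel_rejected(self, noiseless_sim):
        acq, _ = noiseless_sim
        with pytest.raises(IndexError):
            sw.extract_time_profile(acq, 640)

    def test_transverse_profiles_exact_for_noiseless(
        self, noiseless_sim, noiseless_fit
    ):
        acq, truth = noiseless_sim
        profiles = sw.extract_transverse_profiles(acq, noiseless_fit)
        assert [p.label for p in profiles] == ["air", "step1", "step2", "step3", "step4", "step5"]
        # each averaged profile equals the generating level times the air row
        air = profiles[0].values
        levels = np.array(truth["levels"])
        for k, prof in enumerate(profiles[1:], start=1):
            ratio = prof.values[320] / air[320]
            assert ratio == pytest.approx(levels[k], rel=1e-9)

    def test_margins_exclude_slope_rows(self, noiseless_sim, noiseless_fit):
        acq, _ = noiseless_sim
        p = noiseless_fit.p
        for prof in sw.extract_transverse_profiles(acq, noiseless_fit):
            lo, hi = prof.projections_averaged
            if prof.label == "air":
                assert hi - 1 < p[0]
            else:
                k = int(prof.label[-1])
                assert lo > p[2 * k - 1] and hi - 1 < p[2 * k]

    def test_short_segment_rejected(self, noiseless_sim, noiseless_fit, geom, wedge):
        acq, _ = noiseless_sim
        import dataclasses

        bad = dataclasses.replace(noiseless_fit)
        bad.p = noiseless_fit.p.copy()
        bad.p[2] = bad.p[1] + 5.0  # squeeze step-1 flat to 5 projections
        with pytest.raises(SegmentTooShortError, match="step1"):
            sw.extract_transverse_profiles(acq, bad)
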
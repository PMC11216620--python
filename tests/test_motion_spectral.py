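import numpy as np
import pytest

import placentadce as p
from placentadce import chambers as ch
from placentadce import io_preprocess as iop
from placentadce import motion_spectral as ms
from placentadce import perfusion as perf
from placentadce.errors import InvalidInputError, InvalidParameterError

FS = 1.0 / 18.0  # 55.6 mHz


def _blob_pair(shift=1.0, amp=255.0):
    x, y = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    a = amp * np.exp(-(((x - 32) / 6.0) ** 2 + ((y - 32) / 6.0) ** 2))
    b = amp * np.exp(-(((x - 32 - shift) / 6.0) ** 2 + ((y - 32) / 6.0) ** 2))
    return a, b


class TestHornSchunck:
    def test_identical_frames_zero_flow(self, rng):
        frame = rng.random((32, 32)) * 100
        f = p.horn_schunck(frame, frame)
        assert np.all(f.u == 0.0) and np.all(f.v == 0.0)

    def test_recovers_programmed_shift(self):
        a, b = _blob_pair(shift=1.0)
        f = p.horn_schunck(a, b, alpha=100.0, n_iter=400)
        inside = a > 0.3 * a.max()
        assert f.u[inside].mean() == pytest.approx(1.0, rel=0.2)
        assert abs(f.v[inside].mean()) < 0.05

    def test_invariant_to_global_intensity_offset(self):
        a, b = _blob_pair()
        f1 = p.horn_schunck(a, b, n_iter=50)
        f2 = p.horn_schunck(a + 40.0, b + 40.0, n_iter=50)
        assert np.allclose(f1.u, f2.u) and np.allclose(f1.v, f2.v)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(InvalidInputError):
            p.horn_schunck(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_energy_decreases_with_iterations(self):
        a, b = _blob_pair()
        energies = [
            ms.hs_energy(p.horn_schunck(a, b, n_iter=n, tol=0), a, b)
            for n in (1, 5, 20, 100)
        ]
        assert all(e2 <= e1 * (1 + 1e-9) for e1, e2 in zip(energies, energies[1:]))


class TestVelocityTraces:
    def test_zero_fields_zero_traces(self):
        labels = np.ones((6, 6, 1), dtype=np.int32)
        lm = p.SegmentationLabelMap(labels=labels, roles={1: "placenta"})
        vals = np.tile(np.arange(36.0).reshape(6, 6, 1), 1)
        pm = perf.PerfusionMap(f_over_vt=vals, aif_peak=1.0)
        asn = p.assign_chambers(pm, lm, "E14.5")
        u = np.zeros((4, 6, 6, 1))
        traces = p.velocity_traces((u, u.copy()), asn, lm, 18.0)
        assert all(np.all(t.mean_speed == 0.0) for t in traces)

    def test_whole_is_volume_weighted_chamber_mean(self, rng):
        labels = np.ones((6, 6, 1), dtype=np.int32)
        lm = p.SegmentationLabelMap(labels=labels, roles={1: "placenta"})
        pm = perf.PerfusionMap(f_over_vt=rng.random((6, 6, 1)), aif_peak=1.0)
        asn = p.assign_chambers(pm, lm, "E14.5")
        u = rng.random((4, 6, 6, 1))
        v = rng.random((4, 6, 6, 1))
        traces = {t.region: t for t in p.velocity_traces((u, v), asn, lm, 18.0)}
        n_low = asn[1].low_mask.sum()
        n_high = asn[1].high_mask.sum()
        weighted = (
            traces["low"].mean_speed * n_low + traces["high"].mean_speed * n_high
        ) / (n_low + n_high)
        assert np.allclose(traces["whole"].mean_speed, weighted)

    def test_programmed_motion_faster_in_high_chamber(self):
        """Noiseless phantom with motion confined to the high chamber: the
        high-chamber speed trace dominates the low one at moving frames."""
        spec = p.PhantomSpec(
            grid_shape=(48, 48, 4), noise_sigma=0.0, seed=6,
            motion=p.MotionSpec(prevalence=1.0),
        )
        series, _pre, _post, truth = p.synthesize_dce(spec)
        lm = truth.label_map
        den = iop.temporal_denoise(series)
        aif = perf.extract_aif(den, lm)
        clean = den.with_data(iop.spatial_median3(den.data))
        pm = perf.perfusion_map(perf.steepest_slope_map(clean), aif)
        asn = p.assign_chambers(pm, lm, spec.gestational_age)
        flow = p.compute_flow_series(clean, n_iter=60)
        traces = p.velocity_traces(flow, asn, lm, spec.frame_interval)
        by = {}
        for t in traces:
            by.setdefault(t.placenta_id, {})[t.region] = t.mean_speed
        for pid, regions in by.items():
            # compare average speeds over frames with appreciable motion
            moving = regions["high"] > np.percentile(regions["high"], 50)
            assert regions["high"][moving].mean() > regions["low"][moving].mean()


class TestWelchPSD:
    def test_pure_tone_peak(self):
        t = np.arange(200) * 18.0
        x = np.sin(2 * np.pi * 0.010 * t)
        f, psd = p.welch_psd(x, fs=FS)
        assert abs(f[np.argmax(psd)] - 0.010) < 0.0015

    def test_parseval_within_window_bias(self, rng):
        x = rng.standard_normal(256)
        f, psd = p.welch_psd(x, fs=FS)
        df = f[1] - f[0]
        var = np.var(x - x.mean())
        assert np.sum(psd) * df == pytest.approx(var, rel=0.10)

    def test_axis_ends_at_nyquist(self):
        f, _ = p.welch_psd(np.random.default_rng(0).random(50), fs=FS)
        assert f.max() == pytest.approx(FS / 2.0)
        assert f.max() * 1000 == pytest.approx(27.78, abs=0.01)

    def test_oversized_segment_rejected(self):
        with pytest.raises(InvalidParameterError):
            p.welch_psd(np.zeros(20), fs=FS, segment_length=21)


class TestSpectrogram:
    def test_constant_trace_power_at_dc(self):
        f, t, pw = p.spectrogram_stft(np.full(50, 3.0), fs=FS)
        assert np.all(f[np.argmax(pw, axis=0)] == 0.0)

    def test_column_count_framing(self):
        n, L, step = 50, 15, 8  # 50% overlap of a 15-sample window
        _f, t, pw = p.spectrogram_stft(np.zeros(n), fs=FS)
        assert pw.shape[1] == 1 + (n - L) // step == t.size

    def test_tone_switch_on_appears_in_second_half(self):
        t = np.arange(128) * 18.0
        x = np.where(t >= t[64], np.sin(2 * np.pi * 0.012 * t), 0.0)
        f, times, pw = p.spectrogram_stft(x, fs=FS)
        band = (f >= 0.008) & (f <= 0.016)
        band_power = pw[band].sum(axis=0)
        first = band_power[times < t[64]].mean()
        second = band_power[times > t[64]].mean()
        assert second > 10 * first

    def test_short_trace_rejected(self):
        with pytest.raises(InvalidInputError):
            p.spectrogram_stft(np.zeros(10), fs=FS)


class TestSubbandMap:
    def _series(self, data):
        meta = p.AcquisitionMeta(
            frame_interval=18.0, injection_frame=4, tr_ms=101.493, te_ms=1.872,
            flip_angle_deg=75.0, voxel_size=(0.156, 0.156, 0.85),
            n_slices=data.shape[2], n_frames=data.shape[3],
        )
        return p.DCESeries(data=data, meta=meta)

    def test_pure_band_oscillation_near_one(self):
        t = np.arange(64) * 18.0
        data = np.zeros((3, 3, 1, 64))
        data[1, 1, 0] = 5.0 + np.sin(2 * np.pi * 0.010 * t)
        rel = p.subband_relative_power_map(self._series(data))
        assert rel[1, 1, 0] > 0.9

    def test_static_voxel_zero(self):
        data = np.full((3, 3, 1, 64), 2.0)
        rel = p.subband_relative_power_map(self._series(data))
        assert np.all(rel == 0.0)

    def test_affine_rescaling_invariance(self, rng):
        data = rng.random((4, 4, 2, 50))
        rel1 = p.subband_relative_power_map(self._series(data))
        rel2 = p.subband_relative_power_map(self._series(3.7 * data + 11.0))
        assert np.allclose(rel1, rel2, atol=1e-10)

    def test_phantom_motion_localizes_to_high_chamber(self, moving_session):
        (series, _pre, _post, truth), spec = moving_session
        clean = iop.preprocess_series(series)
        rel = p.subband_relative_power_map(clean)
        moving_high = np.zeros_like(truth.chamber_map, dtype=bool)
        for m in truth.true_motion:
            if m.moving:
                moving_high |= (truth.label_map.labels == m.placenta_id) & (
                    truth.chamber_map == 2
                )
        low = truth.chamber_map == 1
        background = truth.label_map.labels == 0
        assert rel[moving_high].mean() > rel[low].mean()
        assert rel[moving_high].mean() > rel[background].mean()


class TestClassifyPhasic:
    def _flags(self, spec):
        series, _pre, _post, truth = p.synthesize_dce(spec)
        den = iop.temporal_denoise(series)
        aif = perf.extract_aif(den, truth.label_map)
        clean = den.with_data(iop.spatial_median3(den.data))
        pm = perf.perfusion_map(perf.steepest_slope_map(clean), aif)
        asn = p.assign_chambers(pm, truth.label_map, spec.gestational_age)
        summary = ms.summarize_subband(
            p.subband_relative_power_map(clean), asn, truth.label_map
        )
        return summary, truth

    def test_zero_motion_phantom_nothing_flagged(self):
        spec = p.PhantomSpec(motion=p.MotionSpec(enabled=False), seed=8)
        summary, _ = self._flags(spec)
        assert sum(p.classify_phasic(summary).values()) == 0

    def test_default_prevalence_recovered(self, moving_session):
        (series, _pre, _post, truth), spec = moving_session
        den = iop.temporal_denoise(series)
        aif = perf.extract_aif(den, truth.label_map)
        clean = den.with_data(iop.spatial_median3(den.data))
        pm = perf.perfusion_map(perf.steepest_slope_map(clean), aif)
        asn = p.assign_chambers(pm, truth.label_map, spec.gestational_age)
        summary = ms.summarize_subband(
            p.subband_relative_power_map(clean), asn, truth.label_map
        )
        flags = p.classify_phasic(summary)
        true_moving = sum(m.moving for m in truth.true_motion)
        assert abs(sum(flags.values()) - true_moving) <= 1

    def test_unreachable_threshold_flags_nothing(self, moving_session):
        (series, _pre, _post, truth), spec = moving_session
        clean = iop.preprocess_series(series)
        pm = perf.perfusion_map(
            perf.steepest_slope_map(clean),
            perf.extract_aif(iop.temporal_denoise(series), truth.label_map),
        )
        asn = p.assign_chambers(pm, truth.label_map, spec.gestational_age)
        summary = ms.summarize_subband(
            p.subband_relative_power_map(clean), asn, truth.label_map
        )
        assert sum(p.classify_phasic(summary, threshold=1.01).values()) == 0
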
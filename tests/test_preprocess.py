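"""Preprocessing chain: reference, filter, epochs, baseline, rejection."""

import numpy as np
import pytest
from scipy import signal as sps

from vepltp import (SimulationConfig, simulate_cohort, simulate_block,
                    rereference_common_average, bandpass_filter, segment,
                    baseline_correct, reject_artifacts, average_epochs,
                    preprocess_recording)
from vepltp.simulate import Recording, EventMarker, standard_montage
from vepltp.preprocess import PreprocessParams, CHAIN_ORDER


def make_recording(data, markers=(), fs=1000.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    labels = [f"ch{i}" for i in range(n)]
    pos = np.zeros((n, 2))
    return Recording(data, fs, labels, pos, list(markers))


class TestRereference:
    def test_already_average_referenced_unchanged(self):
        v = np.sin(np.linspace(0, 10, 500))
        rec = make_recording(np.vstack([v, -v]))
        out = rereference_common_average(rec)
        np.testing.assert_allclose(out.data, rec.data, atol=1e-12)

    def test_common_offset_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 300))
        out0 = rereference_common_average(make_recording(base))
        out1 = rereference_common_average(make_recording(base + 7.5))
        np.testing.assert_allclose(out0.data, out1.data, atol=1e-10)

    def test_channel_mean_is_zero(self):
        rng = np.random.default_rng(1)
        out = rereference_common_average(
            make_recording(rng.normal(size=(4, 1000))))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_pairwise_differences_preserved(self):
        rng = np.random.default_rng(2)
        rec = make_recording(rng.normal(size=(3, 200)))
        out = rereference_common_average(rec)
        np.testing.assert_allclose(out.data[0] - out.data[1],
                                   rec.data[0] - rec.data[1], atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_common_average(make_recording(np.ones((1, 100))))


class TestBandpass:
    # signals span 60 s so the 0.1 Hz high-pass transient (slowest pole
    # time constant ~3.2 s) settles well before the measured core
    fs = 1000.0
    core = slice(15000, -15000)

    def sine(self, hz, seconds=60.0):
        t = np.arange(int(self.fs * seconds)) / self.fs
        return np.sin(2 * np.pi * hz * t)

    def measure_gain(self, hz):
        x = self.sine(hz)
        out = bandpass_filter(make_recording(x), 0.1, 30.0, 3)
        return out.data[0, self.core].std() / x[self.core].std()

    def test_passband_gain_and_zero_lag(self):
        x = self.sine(10.0)
        out = bandpass_filter(make_recording(x), 0.1, 30.0, 3).data[0]
        assert out[self.core].std() / x[self.core].std() >= 0.95
        xc = np.correlate(out[self.core], x[self.core], mode="full")
        lag = int(np.argmax(xc)) - (len(x[self.core]) - 1)
        assert lag == 0

    def test_stopband_gain_matches_transfer_function(self):
        # forward-backward filtering applies |H(f)|^2; predict it first
        sos = sps.butter(3, [0.1, 30.0], btype="bandpass", fs=self.fs,
                         output="sos")
        _, h = sps.sosfreqz(sos, worN=[60.0], fs=self.fs)
        predicted = np.abs(h[0]) ** 2
        measured = self.measure_gain(60.0)
        assert measured < 0.05
        assert measured == pytest.approx(predicted, rel=0.10)

    def test_dc_removed(self):
        out = bandpass_filter(make_recording(np.full(60000, 5.0)), 0.1, 30, 3)
        assert np.abs(out.data[0, self.core]).max() < 1e-6

    def test_impulse_response_time_symmetric(self):
        x = np.zeros(60001)
        x[30000] = 1.0
        out = bandpass_filter(make_recording(x), 0.1, 30, 3).data[0]
        tol = 1e-6 * np.abs(out).max()
        np.testing.assert_allclose(out[30000 - 1000:30000],
                                   out[30000 + 1000:30000:-1], atol=tol)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(make_recording(np.ones((2, 100))), 0.1, 600.0)


def block_markers(n, block="pre", spacing=1100, start=500):
    out = []
    for i in range(2 * n):
        orient = "horizontal" if i % 2 == 0 else "vertical"
        out.append(EventMarker(start + i * spacing, orient, block))
    return out


class TestSegment:
    def test_epoch_counts_and_length(self):
        rng = np.random.default_rng(3)
        n = 12
        markers = block_markers(n)
        total = markers[-1].sample_index + 1000
        rec = make_recording(rng.normal(size=(3, total)), markers)
        cells = segment(rec, "horizontal")
        assert set(cells) == {("pre", "tetanized"), ("pre", "non_tetanized")}
        for ep in cells.values():
            assert ep.n_epochs == n
            assert ep.data.shape[2] == 600
            assert ep.times[0] == -100 and ep.times[-1] == 499

    def test_marker_near_edge_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        markers = [EventMarker(10, "horizontal", "pre")] + block_markers(5)
        total = markers[-1].sample_index + 1000
        rec = make_recording(rng.normal(size=(2, total)), markers)
        with pytest.warns(UserWarning, match="edge"):
            cells = segment(rec, "horizontal")
        assert cells[("pre", "tetanized")].n_epochs == 5

    def test_unknown_orientation_rejected(self):
        rec = make_recording(np.zeros((2, 2000)),
                             [EventMarker(500, "horizontal", "pre")])
        with pytest.raises(ValueError):
            segment(rec, "diagonal")


class TestBaseline:
    def epochs(self, data):
        rec_markers = [EventMarker(100 + i * 700, "horizontal", "pre")
                       for i in range(data.shape[0])]
        flat = np.zeros((data.shape[1], rec_markers[-1].sample_index + 700))
        for m, ep in zip(rec_markers, data):
            flat[:, m.sample_index - 100:m.sample_index + 500] = ep
        rec = make_recording(flat, rec_markers)
        return segment(rec, "horizontal")[("pre", "tetanized")]

    def test_constant_epoch_becomes_zero(self):
        ep = self.epochs(np.full((2, 1, 600), 5.0))
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        ep = self.epochs(rng.normal(size=(3, 2, 600)))
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_linear_ramp_closed_form(self):
        t = np.arange(-100, 500, dtype=float)
        a = 0.02
        ep = self.epochs((a * t)[None, None, :])
        out = baseline_correct(ep)
        expected = a * t - np.mean(a * t[:100])
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-10)

    def test_prestimulus_mean_zero_invariant(self):
        rng = np.random.default_rng(6)
        ep = self.epochs(rng.normal(size=(4, 3, 600)))
        out = baseline_correct(ep)
        pre = out.times < 0
        assert np.abs(out.data[:, :, pre].mean(axis=2)).max() < 1e-12


class TestRejection:
    def clean_epochs(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 5, size=(10, 2, 600))
        markers = [EventMarker(100 + i * 700, "horizontal", "pre")
                   for i in range(10)]
        flat = np.zeros((2, markers[-1].sample_index + 700))
        for m, ep in zip(markers, data):
            flat[:, m.sample_index - 100:m.sample_index + 500] = ep
        rec = make_recording(flat, markers)
        return segment(rec, "horizontal")[("pre", "tetanized")]

    def test_clean_data_not_rejected(self):
        ep, report = reject_artifacts(self.clean_epochs(), 150.0)
        assert report["n_rejected"] == 0 and ep.kept.all()

    def test_spiked_epoch_rejected_exactly(self):
        ep = self.clean_epochs()
        ep.data[4, 1, 300] = 500.0
        out, report = reject_artifacts(ep, 150.0)
        assert report["n_rejected"] == 1
        assert not out.kept[4] and out.kept.sum() == 9

    def test_zero_limit_rejects_all_and_average_fails(self):
        out, report = reject_artifacts(self.clean_epochs(), 0.0)
        assert report["all_rejected"]
        with pytest.raises(ValueError, match="no epochs"):
            average_epochs(out)


class TestAverage:
    def test_identical_epochs_average_to_single_epoch(self):
        base = TestRejection().clean_epochs()
        base.data[:] = base.data[0]
        ev = average_epochs(base)
        np.testing.assert_allclose(ev.data, base.data[0], atol=1e-12)
        assert ev.n_epochs_averaged == base.n_epochs

    def test_kept_mask_respected(self):
        ep = TestRejection().clean_epochs()
        ep.kept[5:] = False
        ev = average_epochs(ep)
        np.testing.assert_allclose(ev.data, ep.data[:5].mean(axis=0))
        assert ev.n_epochs_averaged == 5

    def test_noise_averages_toward_signal_at_clt_rate(self):
        rng = np.random.default_rng(8)
        n, sd = 240, 1.0
        tpl = np.sin(np.linspace(0, 4 * np.pi, 600))
        data = tpl[None, None, :] + rng.normal(0, sd, size=(n, 1, 600))
        ep = TestRejection().clean_epochs()
        times = ep.times
        from vepltp.preprocess import Epochs
        ep = Epochs(data=data, times=times, sampling_rate=1000.0, block="pre",
                    condition="tetanized", kept=np.ones(n, bool),
                    channel_labels=["ch0"], channel_positions=np.zeros((1, 2)))
        ev = average_epochs(ep)
        err = ev.data[0] - tpl
        assert np.sqrt((err ** 2).mean()) < 2 * sd / np.sqrt(n)
        assert np.abs(err).max() < 6 * sd / np.sqrt(n)


class TestChain:
    def small_noiseless(self):
        cfg = SimulationConfig(noise_sd=0.0, n_presentations=6, seed=21,
                               group_sizes=(1, 1, 1))
        sim = simulate_cohort(cfg)
        p = sim.profiles[0]
        return simulate_block(p, "pre", cfg), p.tetanized_orientation

    def test_documented_stage_order(self):
        assert CHAIN_ORDER == ("rereference", "filter", "segment", "baseline",
                               "reject", "average")

    def test_chain_equals_manual_composition(self):
        rec, orientation = self.small_noiseless()
        auto, _ = preprocess_recording(rec, orientation)
        manual = {}
        step = bandpass_filter(rereference_common_average(rec))
        for key, ep in segment(step, orientation).items():
            ep = baseline_correct(ep)
            ep, _ = reject_artifacts(ep, 150.0)
            manual[key] = average_epochs(ep)
        assert set(auto) == set(manual)
        for key in auto:
            np.testing.assert_allclose(auto[key].data, manual[key].data,
                                       atol=1e-12)

    def test_chain_is_linear_in_the_data(self):
        rec, orientation = self.small_noiseless()
        scale = 3.0
        out1, _ = preprocess_recording(rec, orientation)
        scaled = Recording(rec.data * scale, rec.sampling_rate,
                           rec.channel_labels, rec.channel_positions,
                           rec.markers)
        params = PreprocessParams(reject_limit_uv=150.0 * scale)
        out2, _ = preprocess_recording(scaled, orientation, params)
        for key in out1:
            np.testing.assert_allclose(out2[key].data, scale * out1[key].data,
                                       atol=1e-9)
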
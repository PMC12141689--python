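"""Preprocessing-stage contracts: re-referencing, filtering, baseline,
rejection, averaging."""

import numpy as np
import pandas as pd
import pytest

from motionlat.epochs import Epochs
from motionlat.layout import ChannelLayout
from motionlat.preprocess import (average_conditions,
                                  baseline_correct, lowpass_array,
                                  lowpass_filter, preprocess_epochs,
                                  reject_artifacts, rereference_to_mastoids)


def make_epochs(data, layout=None, sfreq=250.0, n_trials=None,
                condition="M_SL"):
    layout = layout or ChannelLayout()
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[np.newaxis]
    n_ep, n_ch, n_t = data.shape
    assert n_ch == len(layout.channels)
    times = -100.0 + (1000.0 / sfreq) * np.arange(n_t)
    info = pd.DataFrame({"subject": "S01", "group": "TC", "handedness": "R",
                         "condition": condition, "trial": np.arange(n_ep)})
    return Epochs(data, info, layout.channels, times, sfreq)


@pytest.fixture
def layout():
    return ChannelLayout()


class TestRereference:
    def test_common_constant_removed_from_scalp(self, layout):
        ep = make_epochs(np.full((len(layout.channels), 50), 7.0), layout)
        out = rereference_to_mastoids(ep, layout)
        scalp = out.channel_index(layout.scalp_channels)
        assert np.allclose(out.data[:, scalp, :], 0.0)

    def test_zero_mastoids_identity(self, layout):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(len(layout.channels), 40))
        m = [layout.channels.index(c) for c in layout.mastoids]
        data[m] = 0.0
        ep = make_epochs(data, layout)
        out = rereference_to_mastoids(ep, layout)
        assert np.allclose(out.data, ep.data)

    def test_channel_differences_invariant(self, layout):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(len(layout.channels), 40))
        ep = make_epochs(data, layout)
        out = rereference_to_mastoids(ep, layout)
        i, j = (layout.channels.index("O1"), layout.channels.index("PO3"))
        assert np.allclose(out.data[:, i] - out.data[:, j],
                           ep.data[:, i] - ep.data[:, j])

    def test_missing_mastoid_errors(self, layout):
        ep = make_epochs(np.zeros((len(layout.channels), 10)), layout)
        ep.channels = [c if c != "M1" else "MX" for c in ep.channels]
        with pytest.raises(KeyError):
            rereference_to_mastoids(ep, layout)


class TestLowpass:
    def test_dc_preserved(self, layout):
        ep = make_epochs(np.full((len(layout.channels), 100), 3.0), layout)
        out = lowpass_filter(ep, 30.0)
        assert np.allclose(out.data, 3.0, atol=1e-9)

    @pytest.mark.parametrize("freq,check", [
        (60.0, lambda ratio: ratio <= 0.10),   # stop band: 2x cutoff
        (5.0, lambda ratio: abs(ratio - 1.0) <= 0.05),  # pass band
    ])
    def test_sinusoid_magnitude_response(self, layout, freq, check):
        """Fourier-magnitude oracle: RMS ratio at the probe frequency."""
        sfreq, n = 250.0, 1000
        t = np.arange(n) / sfreq
        sine = np.sin(2 * np.pi * freq * t)
        out = lowpass_array(np.tile(sine, (1, 1)), sfreq, 30.0, 4)[0]
        spec_in = np.abs(np.fft.rfft(sine))
        spec_out = np.abs(np.fft.rfft(out))
        k = int(round(freq * n / sfreq))
        assert check(spec_out[k] / spec_in[k])

    def test_cutoff_above_nyquist_rejected(self, layout):
        ep = make_epochs(np.zeros((len(layout.channels), 20)), layout)
        with pytest.raises(ValueError):
            lowpass_filter(ep, 130.0)

    def test_zero_phase_peak_unshifted(self, layout):
        sfreq = 250.0
        times = np.arange(200) / sfreq
        gauss = np.exp(-0.5 * ((times - 0.4) / 0.02) ** 2)
        out = lowpass_array(gauss[np.newaxis], sfreq, 30.0, 4)[0]
        assert abs(int(np.argmax(out)) - int(np.argmax(gauss))) <= 1


class TestBaseline:
    def test_constant_trial_zeroed(self, layout):
        ep = make_epochs(np.full((len(layout.channels), 275), 7.0), layout)
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_idempotent_on_zero_mean_window(self, layout):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.normal(size=(len(layout.channels), 275)), layout)
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data)
        mask = (ep.times >= -100) & (ep.times < 0)
        assert np.allclose(once.data[:, :, mask].mean(axis=2), 0.0,
                           atol=1e-12)

    def test_ramp_slope_preserved_window_mean_zero(self, layout):
        times = -100.0 + 4.0 * np.arange(275)
        ramp = 2.0 + 0.3 * times
        data = np.tile(ramp, (len(layout.channels), 1))
        out = baseline_correct(make_epochs(data, layout))
        # closed form: subtracting the window mean leaves slope intact
        slopes = np.diff(out.data[0, 0]) / 4.0
        assert np.allclose(slopes, 0.3)
        mask = (out.times >= -100) & (out.times < 0)
        assert abs(out.data[0, 0, mask].mean()) < 1e-12

    def test_empty_window_rejected(self, layout):
        ep = make_epochs(np.zeros((len(layout.channels), 10)), layout)
        with pytest.raises(ValueError):
            baseline_correct(ep, window=(500.0, 600.0))


class TestRejection:
    def test_spiked_trials_removed(self, layout):
        n_ch = len(layout.channels)
        data = np.zeros((110, n_ch, 50))
        spike_ch = layout.channels.index("O1")
        data[:10, spike_ch, 25] = 250.0
        ep = make_epochs(data, layout)
        kept, log = reject_artifacts(ep, layout)
        assert kept.n_epochs == 100
        assert (log.reason[:10] == "amplitude").all()

    def test_exact_threshold_retained(self, layout):
        n_ch = len(layout.channels)
        data = np.zeros((1, n_ch, 50))
        data[0, layout.channels.index("O1"), 10] = 200.0
        kept, log = reject_artifacts(make_epochs(data, layout), layout)
        assert kept.n_epochs == 1 and log.reason.iloc[0] == "none"

    def test_eog_peak_to_peak_criteria(self, layout):
        n_ch = len(layout.channels)
        data = np.zeros((3, n_ch, 50))
        data[0, layout.channels.index("HEOG"), 25:] = 41.0
        data[1, layout.channels.index("VEOG"), 20:30] = 101.0
        kept, log = reject_artifacts(make_epochs(data, layout), layout)
        assert list(log.reason) == ["HEM", "VEOG", "none"]
        assert kept.n_epochs == 1

    def test_counts_reconcile(self, layout):
        rng = np.random.default_rng(3)
        n_ch = len(layout.channels)
        data = rng.normal(scale=80, size=(50, n_ch, 60))
        kept, log = reject_artifacts(make_epochs(data, layout), layout)
        assert kept.n_epochs + (log.reason != "none").sum() == 50
        assert (log.retained == (log.reason == "none")).all()

    def test_all_rejected_warns(self, layout):
        n_ch = len(layout.channels)
        data = np.full((5, n_ch, 20), 300.0)
        data[:, [layout.channels.index(c)
                 for c in layout.mastoids]] = 300.0
        with pytest.warns(UserWarning, match="all trials"):
            reject_artifacts(make_epochs(data, layout), layout)

    def test_simulator_truth_flags_recovered(self, layout):
        """Rejection reaches >=0.95 sensitivity and specificity against
        the simulator's planted artifact flags at default thresholds."""
        from motionlat.config import scaled_config
        from motionlat.simulate import CohortSimulator

        cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=250,
                            artifact_rate=0.4, seed=42)
        sim = CohortSimulator(cfg, layout)
        truth = sim.truth()
        ep = sim.epochs(truth, conditions=("M_SL",))   # 1000 trials
        x = baseline_correct(rereference_to_mastoids(ep, layout))
        _, log = reject_artifacts(x, layout)
        rejected = ~log.retained
        sens = (rejected & log.artifact_true).sum() / log.artifact_true.sum()
        spec = (log.retained & ~log.artifact_true).sum() \
            / (~log.artifact_true).sum()
        assert sens >= 0.95 and spec >= 0.95


class TestAveraging:
    def test_two_trial_mean(self, layout):
        n_ch = len(layout.channels)
        data = np.stack([np.full((n_ch, 20), 1.0), np.full((n_ch, 20), 3.0)])
        avgs = average_conditions(make_epochs(data, layout), min_trials=1)
        assert np.allclose(avgs.data[0], 2.0)
        assert avgs.table.n_trials_used.iloc[0] == 2

    def test_identical_trials_average_to_trial(self, layout):
        rng = np.random.default_rng(4)
        trial = rng.normal(size=(len(layout.channels), 30))
        data = np.stack([trial] * 5)
        avgs = average_conditions(make_epochs(data, layout), min_trials=1)
        assert np.allclose(avgs.data[0], trial)

    def test_noise_averages_toward_signal_clt(self, layout):
        rng = np.random.default_rng(5)
        n, sd = 400, 8.0
        signal = np.linspace(-1, 1, 30)
        data = signal + rng.normal(scale=sd,
                                   size=(n, len(layout.channels), 30))
        avgs = average_conditions(make_epochs(data, layout), min_trials=1)
        assert np.abs(avgs.data[0] - signal).max() < 5 * sd / np.sqrt(n)

    def test_low_trial_flagging(self, layout):
        data = np.zeros((3, len(layout.channels), 10))
        avgs = average_conditions(make_epochs(data, layout), min_trials=40)
        assert avgs.table.low_trials.all()


def test_reference_invariance_of_downstream_measures(layout):
    """Adding a common waveform to every channel (mastoids included) leaves
    component measures unchanged after the default chain."""
    from motionlat.components import ComponentExtractor
    from motionlat.config import scaled_config
    from motionlat.simulate import CohortSimulator

    cfg = scaled_config({"TC": 2, "WS": 2}, n_trials=4, noise_sd=0.0,
                        artifact_rate=0.0, seed=43)
    sim = CohortSimulator(cfg, layout)
    truth = sim.truth().iloc[[0]]
    ep = sim.epochs(truth, with_artifacts=False)
    common = np.sin(2 * np.pi * 7 * np.arange(len(ep.times)) / 250.0) * 20
    shifted = ep.copy()
    shifted.data = shifted.data + common
    base = ComponentExtractor(layout).transform(
        preprocess_epochs(ep, layout))
    moved = ComponentExtractor(layout).transform(
        preprocess_epochs(shifted, layout))
    assert np.allclose(base.mean_amplitude_uV, moved.mean_amplitude_uV,
                       atol=1e-9)
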
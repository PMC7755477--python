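"""Conditioning-chain tests: re-reference, interpolation, filter, epoching."""

import numpy as np
import pytest

from transfercsp import (ConfigurationError, ContinuousRecord, DataError,
                         InterpolationError, bandpass_8_30, baseline_correct,
                         default_neighbor_map, extract_epochs,
                         interpolate_bad_channels, make_montage, preprocess,
                         rereference_linked_mastoids, simulate_session,
                         to_continuous)
from transfercsp.synthetic import EpochSet
from tests.conftest import quick_config


def make_record(data, fs=500.0, events=(), reference="LM"):
    montage = make_montage(data.shape[0])
    return ContinuousRecord(np.asarray(data, float), fs, montage,
                            list(events), reference)


class TestRereference:
    def test_zero_mastoid_is_identity(self, rng):
        data = rng.standard_normal((8, 100))
        rec = make_record(data)
        data[rec.montage.index("RM")] = 0.0
        out = rereference_linked_mastoids(make_record(data))
        assert np.array_equal(out.data, data)

    def test_half_mastoid_subtracted(self):
        data = np.full((8, 4), 4.0)
        rec = make_record(data)
        data[rec.montage.index("RM")] = 2.0
        out = rereference_linked_mastoids(make_record(data))
        ch = out.montage.index("C3")
        assert np.allclose(out.data[ch], 3.0)  # 4 - 2/2
        assert out.reference == "linked-mastoids"

    def test_second_application_rejected(self, rng):
        rec = make_record(rng.standard_normal((8, 10)))
        once = rereference_linked_mastoids(rec)
        with pytest.raises(ConfigurationError):
            rereference_linked_mastoids(once)


class TestInterpolation:
    def test_no_bad_channels_is_identity(self, rng):
        rec = make_record(rng.standard_normal((8, 20)))
        out = interpolate_bad_channels(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_constant_field_preserved(self):
        rec = make_record(np.ones((8, 10)))
        out = interpolate_bad_channels(rec, ["Cz"])
        assert np.allclose(out.data[rec.montage.index("Cz")], 1.0)

    def test_mean_of_neighbors(self):
        rec = make_record(np.zeros((8, 5)))
        nmap = {"C3": ["C4", "Cz"]}
        rec.data[rec.montage.index("C4")] = 2.0
        rec.data[rec.montage.index("Cz")] = 4.0
        out = interpolate_bad_channels(rec, ["C3"], nmap)
        assert np.allclose(out.data[rec.montage.index("C3")], 3.0)
        others = [i for i, c in enumerate(rec.montage.channel_names)
                  if c != "C3"]
        assert np.array_equal(out.data[others], rec.data[others])

    def test_all_bad_neighborhood_rejected(self, rng):
        rec = make_record(rng.standard_normal((8, 5)))
        nmap = {"C3": ["C4", "Cz"], "C4": ["C3", "Cz"], "Cz": ["C3", "C4"]}
        with pytest.raises(InterpolationError):
            interpolate_bad_channels(rec, ["C3", "C4", "Cz"], nmap)

    def test_default_neighbor_map_uses_geometry(self):
        nmap = default_neighbor_map(make_montage(64), k=4)
        assert len(nmap) == 64
        assert all(len(v) == 4 for v in nmap.values())
        assert "C3" not in nmap["C3"]


class TestBandpass:
    def test_passband_tone_preserved(self):
        fs, t = 500.0, np.arange(5000) / 500.0
        tone = np.sin(2 * np.pi * 15 * t)
        rec = make_record(np.tile(tone, (8, 1)), fs=fs)
        out = bandpass_8_30(rec).data[0][500:-500]
        assert abs(out.std() - tone[500:-500].std()) / tone.std() < 0.1

    def test_stopband_tone_attenuated(self):
        fs, t = 500.0, np.arange(5000) / 500.0
        tone = np.sin(2 * np.pi * 50 * t)
        rec = make_record(np.tile(tone, (8, 1)), fs=fs)
        assert bandpass_8_30(rec).data[0][500:-500].std() < tone.std() / 10

    def test_dc_offset_removed(self):
        rec = make_record(np.full((8, 2000), 100.0))
        assert abs(bandpass_8_30(rec).data.mean()) < 1e-6

    def test_low_sampling_rate_rejected(self, rng):
        rec = make_record(rng.standard_normal((8, 100)), fs=50.0)
        with pytest.raises(ConfigurationError):
            bandpass_8_30(rec)

    def test_epochs_dispatch_preserves_labels(self, quick_session):
        epochs, _ = quick_session
        out = bandpass_8_30(epochs)
        assert isinstance(out, EpochSet)
        assert np.array_equal(out.labels, epochs.labels)
        assert out.data.shape == epochs.data.shape


class TestEpoching:
    def test_default_window_is_1250_samples_at_500hz(self, rng):
        data = rng.standard_normal((8, 3000))
        rec = make_record(data, fs=500.0, events=[(1000, "LH")])
        ep = extract_epochs(rec, -0.5, 2.0)
        assert ep.n_samples == 1250  # (2.0 - (-0.5)) * 500, half-open
        assert ep.t0_offset_s == -0.5
        assert np.array_equal(ep.data[0], data[:, 750:2000])

    def test_single_sample_window(self, rng):
        rec = make_record(rng.standard_normal((8, 100)), fs=500.0,
                          events=[(50, "RH")])
        ep = extract_epochs(rec, 0.0, 0.002)
        assert ep.n_samples == 1

    def test_truncated_window_reports_event(self, rng):
        rec = make_record(rng.standard_normal((8, 600)), fs=500.0,
                          events=[(300, "LH"), (580, "RH")])
        with pytest.raises(DataError, match="580"):
            extract_epochs(rec, -0.5, 2.0)

    def test_labels_follow_events(self, rng):
        events = [(100 + 50 * i, c) for i, c in enumerate("ABAB")]
        rec = make_record(rng.standard_normal((8, 500)), fs=100.0,
                          events=events)
        ep = extract_epochs(rec, 0.0, 0.2)
        assert list(ep.labels) == list("ABAB")


class TestBaseline:
    def test_constant_trial_zeroed(self):
        ep = EpochSet(np.full((2, 8, 100), 5.0), np.array(["a", "b"]), 100.0,
                      make_montage(8), t0_offset_s=-0.5)
        assert np.allclose(baseline_correct(ep).data, 0.0)

    def test_subtracts_baseline_mean(self):
        data = np.zeros((1, 8, 100))
        data[:, :, :50] = 2.0  # pre-cue
        data[:, :, 50:] = 7.0  # post-cue
        ep = EpochSet(data, np.array(["a"]), 100.0, make_montage(8), -0.5)
        out = baseline_correct(ep)
        assert np.allclose(out.data[:, :, 50:], 5.0)

    def test_idempotent(self, quick_session):
        epochs, _ = quick_session
        once = baseline_correct(epochs)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data)

    def test_interval_outside_window_rejected(self, quick_session):
        epochs, _ = quick_session
        with pytest.raises(ConfigurationError):
            baseline_correct(epochs, interval=(-2.0, -1.0))


class TestChain:
    def test_full_chain_preserves_trials_and_labels(self):
        epochs, _ = simulate_session(quick_config(n_trials_per_class=4,
                                                  trial_len_s=2.6))
        rec = to_continuous(epochs, gap_s=1.0)
        out = preprocess(rec, bad_channels=["Cz"], tmin_s=-0.5, tmax_s=2.0)
        assert out.n_trials == epochs.n_trials
        assert np.array_equal(np.sort(out.labels), np.sort(epochs.labels))
        assert out.n_channels == epochs.n_channels
        assert out.n_samples == int(2.5 * epochs.fs)

    def test_out_of_band_contaminants_do_not_change_class_structure(self):
        # adding strong 2 Hz and 60 Hz components upstream of the band-pass
        # leaves the downstream decisions essentially unchanged
        from transfercsp import (covariance_pair, csp_filters,
                                 extract_features, predict, train_classifier)

        epochs, _ = simulate_session(quick_config(n_trials_per_class=20,
                                                  fs=250.0, seed=4))
        t = np.arange(epochs.n_samples) / epochs.fs
        contaminated = EpochSet(
            epochs.data + 50 * np.sin(2 * np.pi * 2 * t)
            + 20 * np.sin(2 * np.pi * 60 * t),
            epochs.labels, epochs.fs, epochs.montage, epochs.t0_offset_s)
        preds = {}
        for name, ep in [("clean", epochs), ("dirty", contaminated)]:
            filt = bandpass_8_30(ep)
            train, test = filt.select(np.arange(0, 40, 2)), filt.select(
                np.arange(1, 40, 2))
            bank = csp_filters(covariance_pair(train, "LH", "RH"))
            reduced = bank.take([0, 1, bank.n_filters - 2, bank.n_filters - 1])
            model = train_classifier(extract_features(reduced, train), seed=0)
            preds[name] = predict(model, extract_features(reduced, test))
        agreement = np.mean(preds["clean"] == preds["dirty"])
        assert agreement >= 0.9
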
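"""Filtering, epoching, artifact rejection and re-referencing."""

import numpy as np
import pandas as pd
import pytest

from prestim.containers import EpochSet, Recording
from prestim.preprocessing import (bandpass, common_average_reference, epoch,
                                   ica_hook, preprocess_recording,
                                   zscore_artifact_reject)


def _sine_recording(freq, sfreq=500.0, dur=10.0, n_ch=3, dc=0.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    data = np.tile(np.sin(2 * np.pi * freq * t) + dc, (n_ch, 1))
    return Recording(data=data, sfreq=sfreq,
                     ch_names=[f"ch{i}" for i in range(n_ch)])


class TestBandpass:
    def test_stopband_attenuation(self):
        rec = _sine_recording(60.0)
        out = bandpass(rec, 0.5, 40.0)
        mid = slice(1000, -1000)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio < 0.10

    def test_passband_preserved(self):
        rec = _sine_recording(10.0)
        out = bandpass(rec, 0.5, 40.0)
        mid = slice(1000, -1000)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_dc_removed(self):
        rec = _sine_recording(10.0, dc=100.0)
        out = bandpass(rec, 0.5, 40.0)
        assert abs(out.data[0, 1000:-1000].mean()) < 1.0

    def test_band_outside_nyquist_rejected(self):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, 0.5, 400.0)


class TestEpoch:
    def test_window_sample_count(self):
        rec = _sine_recording(5.0, dur=900.0, n_ch=2)
        onsets = (np.arange(141) * 6.0 + 5.0) * 500
        ep = epoch(rec, onsets.astype(int))
        assert ep.n_trials == 141
        assert ep.data.shape[2] == 2950
        # sample index of stimulus onset
        onset_idx = int(round(-ep.t_start * ep.sfreq))
        assert ep.times[onset_idx] == pytest.approx(0.0, abs=1e-9)

    def test_empty_marker_list(self):
        rec = _sine_recording(5.0)
        ep = epoch(rec, np.array([], dtype=int))
        assert ep.n_trials == 0

    def test_edge_marker_flagged_not_dropped(self):
        rec = _sine_recording(5.0, dur=10.0)
        ep = epoch(rec, np.array([int(1.0 * 500), int(5.0 * 500)]))
        assert ep.n_trials == 2
        assert ep.rejected[0] == "edge"   # needs 3.4 s of pre-data
        assert ep.rejected[1] is None


class TestZScoreRejection:
    def test_clean_rejection_fraction_low(self, small_epochs):
        out = zscore_artifact_reject(small_epochs, exclude=())
        assert (~out.kept_mask).mean() <= 0.05

    def test_infinite_thresholds_keep_everything(self, small_epochs):
        out = zscore_artifact_reject(small_epochs, np.inf, np.inf,
                                     exclude=())
        assert out.kept_mask.all()

    def test_too_few_trials_error(self, small_epochs):
        single = EpochSet(
            data=small_epochs.data[:1], sfreq=small_epochs.sfreq,
            t_start=small_epochs.t_start, t_end=small_epochs.t_end,
            ch_names=small_epochs.ch_names,
        )
        with pytest.raises(ValueError, match="2 usable trials"):
            zscore_artifact_reject(single, exclude=())

    def test_permutation_equivariance(self, small_epochs):
        """Reordering trials permutes the rejection flags identically."""
        from prestim.simulate import inject_artifacts

        data = small_epochs.data.copy()
        data[4], _ = inject_artifacts(
            data[4], {"jump": 1.0}, np.random.default_rng(0),
            sfreq=small_epochs.sfreq, ch_names=small_epochs.ch_names,
        )
        perm = np.random.default_rng(1).permutation(data.shape[0])

        def flags(arr):
            ep = EpochSet(data=arr, sfreq=small_epochs.sfreq,
                          t_start=small_epochs.t_start,
                          t_end=small_epochs.t_end,
                          ch_names=small_epochs.ch_names)
            return np.array(zscore_artifact_reject(ep, exclude=()).rejected,
                            dtype=object)

        assert np.array_equal(flags(data)[perm], flags(data[perm]))

    def test_detection_sensitivity_and_false_rate(self, posterior_config):
        """On epochs with known artifact logs, >= 90% of contaminated
        trials are flagged and <= 10% of clean trials are falsely flagged."""
        import dataclasses

        from prestim.simulate import simulate_eeg_epochs

        cfg = dataclasses.replace(
            posterior_config,
            artifact_rates={"jump": 0.25, "muscle": 0.25, "blink": 0.0},
        )
        epochs, log = simulate_eeg_epochs(
            cfg, "ne", np.random.default_rng(13), n_trials=60, inject=True
        )
        contaminated = {e["trial"] for e in log}
        out = zscore_artifact_reject(epochs, exclude=())
        flagged = {i for i, r in enumerate(out.rejected) if r is not None}
        hit = len(flagged & contaminated) / max(len(contaminated), 1)
        clean = set(range(60)) - contaminated
        false = len(flagged & clean) / max(len(clean), 1)
        assert hit >= 0.9
        assert false <= 0.1


class TestCommonAverage:
    def test_scalp_mean_zero_and_eog_untouched(self, small_epochs):
        eog = small_epochs.ch_names[-1]
        out = common_average_reference(small_epochs, exclude=[eog])
        scalp = [i for i, c in enumerate(out.ch_names) if c != eog]
        assert np.abs(out.data[:, scalp].mean(axis=1)).max() < 1e-10
        i_eog = out.ch_names.index(eog)
        assert np.array_equal(out.data[:, i_eog], small_epochs.data[:, i_eog])

    def test_idempotent(self, small_epochs):
        once = common_average_reference(small_epochs, exclude=())
        twice = common_average_reference(once, exclude=())
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_all_excluded_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            common_average_reference(small_epochs,
                                     exclude=small_epochs.ch_names)


def test_ica_hook_passthrough_and_substitution(small_epochs):
    assert ica_hook(small_epochs) is small_epochs
    halved = ica_hook(
        small_epochs,
        cleaner=lambda ep: EpochSet(
            data=ep.data / 2, sfreq=ep.sfreq, t_start=ep.t_start,
            t_end=ep.t_end, ch_names=ep.ch_names,
        ),
    )
    assert np.allclose(halved.data, small_epochs.data / 2)


def test_preprocess_recording_end_to_end(posterior_config):
    from prestim.simulate import simulate_participant_eeg

    rec, _ = simulate_participant_eeg(
        posterior_config, "ne", np.random.default_rng(21), n_trials=5
    )
    ep = preprocess_recording(rec)
    assert ep.n_trials == 5
    scalp_mean = ep.data[:, [ep.ch_names.index(c) for c in ep.ch_names
                             if not c.startswith("EOG")]].mean(axis=1)
    assert np.abs(scalp_mean).max() < 1e-9
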
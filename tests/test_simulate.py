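"""Synthetic cohort generator: EEG structure, SDT behaviour, artifacts."""

import numpy as np
import pandas as pd
import pytest

from prestim.simulate import (CohortConfig, inject_artifacts,
                              simulate_behavior, simulate_eeg_epochs,
                              simulate_eeg_trial, simulate_participant,
                              simulate_participant_eeg)


class TestEEGTrial:
    def test_segment_shape_and_determinism(self, posterior_config):
        seg1 = simulate_eeg_trial(posterior_config, "theta",
                                  np.random.default_rng(1))
        seg2 = simulate_eeg_trial(posterior_config, "theta",
                                  np.random.default_rng(1))
        n_samp = int(round(5.9 * posterior_config.sampling_rate))
        assert seg1.shape == (len(posterior_config.channel_labels), n_samp)
        assert np.array_equal(seg1, seg2)

    def test_unknown_group_rejected(self, posterior_config):
        with pytest.raises(ValueError, match="group"):
            simulate_eeg_trial(posterior_config, "gamma",
                               np.random.default_rng(0))

    def test_zero_amplitude_matches_ne_band_power(self):
        """With the entrained amplitude at zero, theta-group trials carry
        no extra 5 Hz band power relative to NE trials."""
        cfg = CohortConfig(channel_labels=["O1", "Oz", "O2"],
                           entrain_amplitude=0.0)
        rng = np.random.default_rng(9)

        def band_power(group):
            powers = []
            for _ in range(40):
                seg = simulate_eeg_trial(cfg, group, rng)
                # late stimulation window, -1.1 .. -0.1 s
                sl = seg[:, int(2.3 * 500):int(3.3 * 500)]
                spec = np.abs(np.fft.rfft(sl, axis=1)) ** 2
                freqs = np.fft.rfftfreq(sl.shape[1], 1 / 500.0)
                powers.append(spec[:, (freqs >= 4) & (freqs <= 6)].sum())
            return np.array(powers)

        from scipy import stats
        t, p = stats.ttest_ind(band_power("theta"), band_power("ne"))
        assert p > 0.01

    def test_entrained_band_power_elevated(self, theta_epochs):
        """Theta-group trials at default amplitude show clearly elevated
        5 Hz power over occipital channels in the late window."""
        from prestim.entrainment import assess_entrainment
        from prestim.timefreq import baseline_percent_change, tfr_hanning

        pc = baseline_percent_change(tfr_hanning(theta_epochs))
        a = assess_entrainment(pc, 5.0)
        assert a.passed
        assert a.max_percent_change > 10.0


class TestContinuousRecording:
    def test_markers_strictly_increasing_one_per_trial(self, posterior_config):
        rec, _ = simulate_participant_eeg(
            posterior_config, "alpha", np.random.default_rng(3), n_trials=6
        )
        stim = rec.event_samples("stim_onset")
        entrain = rec.event_samples("entrain_onset")
        assert len(stim) == 6 and len(entrain) == 6
        assert (np.diff(stim) > 0).all()
        # entrainment markers precede their stimulus by 2.1 s
        assert np.allclose(stim - entrain, 2.1 * rec.sfreq)

    def test_determinism(self, posterior_config):
        r1, _ = simulate_participant_eeg(posterior_config, "control",
                                         np.random.default_rng(5), n_trials=3)
        r2, _ = simulate_participant_eeg(posterior_config, "control",
                                         np.random.default_rng(5), n_trials=3)
        assert np.array_equal(r1.data, r2.data)


class TestBehavior:
    def test_row_count_two_per_encoding_trial(self):
        cfg = CohortConfig(runs=3, encoding_trials_per_run=47)
        table, _ = simulate_behavior(cfg, "alpha", np.random.default_rng(0))
        assert len(table) == 282
        per_run = table.groupby("run").size()
        assert (per_run == 94).all()
        assert (table.groupby("run")["status"]
                .value_counts().eq(47).all())

    def test_null_model_symmetric_rates(self):
        cfg = CohortConfig(runs=10, encoding_trials_per_run=200,
                           criterion_c=0.0, p_missed=0.0)
        table, _ = simulate_behavior(cfg, "ne", np.random.default_rng(4),
                                     dprime=0.0)
        old = table[table.status == "old"]
        new = table[table.status == "new"]
        hit = (old.response == "old").mean()
        fa = (new.response == "old").mean()
        assert hit == pytest.approx(0.5, abs=0.03)
        assert fa == pytest.approx(0.5, abs=0.03)

    def test_extreme_criterion_all_new(self):
        cfg = CohortConfig(criterion_c=1e9, p_missed=0.0)
        table, _ = simulate_behavior(cfg, "theta", np.random.default_rng(0))
        assert (table.response == "new").all()

    def test_group_mean_dprime_recovered(self):
        """Large-sample mean of drawn d' values approaches the group mean
        (mild upward shift from zero-truncation is below sampling error)."""
        cfg = CohortConfig()
        rng = np.random.default_rng(11)
        draws = [simulate_behavior(cfg, "alpha", rng)[1]["true_dprime"]
                 for _ in range(300)]
        assert np.mean(draws) == pytest.approx(1.46, abs=0.09)


class TestArtifacts:
    def test_zero_rates_leave_segment_unchanged(self, posterior_config):
        seg = simulate_eeg_trial(posterior_config, "ne",
                                 np.random.default_rng(0))
        out, log = inject_artifacts(seg, {}, np.random.default_rng(1))
        assert np.array_equal(out, seg)
        assert log == []

    def test_same_seed_same_placement(self, posterior_config):
        seg = simulate_eeg_trial(posterior_config, "ne",
                                 np.random.default_rng(0))
        rates = {"jump": 1.0, "muscle": 1.0, "blink": 1.0}
        out1, log1 = inject_artifacts(seg, rates, np.random.default_rng(42))
        out2, log2 = inject_artifacts(seg, rates, np.random.default_rng(42))
        assert np.array_equal(out1, out2)
        assert log1 == log2

    def test_jump_round_trip_rejected(self, small_epochs):
        """A 500 uV step injected into one trial drives its accumulated
        z-score past the jump cutoff of 60."""
        from prestim.containers import EpochSet
        from prestim.preprocessing import zscore_artifact_reject

        data = small_epochs.data.copy()
        data[7], log = inject_artifacts(
            data[7], {"jump": 1.0}, np.random.default_rng(8),
            sfreq=small_epochs.sfreq, ch_names=small_epochs.ch_names,
        )
        assert log[0]["type"] == "jump"
        contaminated = EpochSet(
            data=data, sfreq=small_epochs.sfreq,
            t_start=small_epochs.t_start, t_end=small_epochs.t_end,
            ch_names=small_epochs.ch_names,
        )
        out = zscore_artifact_reject(contaminated, exclude=())
        assert out.rejected[7] == "jump"
        score = out.rejection_scores.set_index("trial").loc[7, "jump_z"]
        assert score > 60


def test_simulate_participant_bundles_everything(posterior_config):
    from numpy.random import SeedSequence

    p = simulate_participant(posterior_config, "theta", "theta_000",
                             SeedSequence(99), n_trials=3)
    assert p.eeg.data.shape[0] == len(posterior_config.channel_labels)
    assert len(p.behavior) == 2 * 3 * 47
    assert p.truth["true_dprime"] >= 0
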
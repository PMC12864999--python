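"""Synthetic EEG cohorts with the statistical structure the analysis assumes.

Each simulated participant consists of (a) a continuous 64-channel EEG
recording at 500 Hz with event markers at entrainment onset and stimulus
onset, and (b) a per-trial recognition behaviour table generated from an
equal-variance signal-detection model.

The EEG model is additive: 1/f^chi background noise per channel, ongoing
~10 Hz alpha with random phase, a narrow-band entrained component at the
group's stimulation frequency during the pre-stimulus stimulation window
(amplitude rising exponentially toward a plateau, spatially peaked over
O1/O2/Oz), and a damped evoked transient after stimulus onset.  The
no-entrainment (NE) group lacks the entrained component; the arhythmic
control is driven by a participant-specific chain of single 13-24 Hz
cycles, mirroring the stimulus construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet, Recording
from .waveforms import make_arhythmic_waveform

# 60 scalp channels (10-10 names) + 4 EOG channels.
SCALP_CHANNELS = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]
EOG_CHANNELS = ["EOG1", "EOG2", "EOG3", "EOG4"]
DEFAULT_CHANNELS = SCALP_CHANNELS + EOG_CHANNELS

GROUP_FREQUENCIES = {"theta": 5.0, "alpha": 9.0}
VALID_GROUPS = ("theta", "alpha", "control", "ne")

#: Group-level d' distributions (mean, SD) reported for the four cohorts.
DEFAULT_DPRIME = {
    "theta": (1.28, 0.55),
    "alpha": (1.46, 0.60),
    "control": (1.18, 0.50),
    "ne": (1.27, 0.53),
}

# Trial timing relative to stimulus onset (seconds).
TRIAL_T_START = -3.4
TRIAL_T_END = 2.5
ENTRAIN_ONSET = -2.1  # stimulation begins 2.1 s before stimulus onset


@dataclass
class CohortConfig:
    """Parameters of a simulated cohort; defaults follow the study design."""

    groups: tuple = VALID_GROUPS
    k_per_group: int = 35
    runs: int = 3
    encoding_trials_per_run: int = 47
    sampling_rate: float = 500.0
    channel_labels: list = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    entrain_amplitude: float = 6.0       # microvolts at the occipital peak
    entrain_ramp_tau: float = 0.5        # seconds, build-up time constant
    noise_exponent: float = 1.0          # chi of the 1/f^chi background
    noise_std: float = 10.0              # microvolts per channel
    alpha_amplitude: float = 4.0         # ongoing alpha, microvolts
    alpha_freq: float = 10.0
    evoked_amplitude: float = 5.0        # post-onset transient, microvolts
    dprime_mean_sd_per_group: dict = field(
        default_factory=lambda: dict(DEFAULT_DPRIME)
    )
    criterion_c: float = 1.13            # SDT response bias (FA ~ 13%)
    p_missed: float = 0.01               # missed-response probability
    artifact_rates: dict = field(
        default_factory=lambda: {"jump": 0.0, "muscle": 0.0, "blink": 0.0}
    )
    trial_spacing_s: float = 8.0         # onset-to-onset interval
    ne_pool_k: int = 45                  # NE cohort size before matching
    rt_mu: float = -0.45                 # shifted-lognormal RT parameters
    rt_sigma: float = 0.35
    rt_shift_s: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_per_group < 1:
            raise ValueError("k_per_group must be >= 1")
        if self.encoding_trials_per_run < 1:
            raise ValueError("encoding_trials_per_run must be >= 1")
        for g in self.groups:
            if g not in VALID_GROUPS:
                raise ValueError(f"unknown group {g!r}")

    @property
    def scalp_channels(self) -> list:
        return [c for c in self.channel_labels if c not in EOG_CHANNELS]


@dataclass
class SimulatedParticipant:
    participant_id: str
    group: str
    eeg: Recording
    behavior: pd.DataFrame
    truth: dict


def _channel_weights(ch_names) -> np.ndarray:
    """Posterior-peaked spatial profile of the visually driven components."""
    w = np.empty(len(ch_names))
    for i, ch in enumerate(ch_names):
        if ch in ("O1", "O2", "Oz"):
            w[i] = 1.0
        elif ch.startswith("PO"):
            w[i] = 0.7
        elif ch.startswith("P") and not ch.startswith("PO"):
            w[i] = 0.4
        elif ch.startswith(("CP", "TP")):
            w[i] = 0.15
        elif ch.startswith("EOG"):
            w[i] = 0.0
        else:
            w[i] = 0.05
    return w


def pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sfreq: float,
    exponent: float = 1.0,
    std: float = 10.0,
) -> np.ndarray:
    """1/f^chi background: spectrally shaped white noise, unit-std scaled."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    s = shaped.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return shaped / s * std


def _entrain_drive(
    config: CohortConfig,
    group: str,
    t: np.ndarray,
    arhythmic_chain: Optional[np.ndarray] = None,
    chain_rate: float = 1000.0,
) -> np.ndarray:
    """Zero-mean narrow-band drive over the stimulation window, ramped.

    ``t`` is in seconds relative to stimulus onset.  Returns the time course
    at the occipital peak (amplitude ``entrain_amplitude``); callers scale
    by the spatial profile.
    """
    drive = np.zeros_like(t)
    if group == "ne":
        return drive
    if group in GROUP_FREQUENCIES:
        f = GROUP_FREQUENCIES[group]
        gap_s = 1.0 / (2.0 * f)
        on, off = ENTRAIN_ONSET, -gap_s
        mask = (t >= on) & (t < off)
        # phase-locked to stimulation onset
        drive[mask] = np.sin(2.0 * np.pi * f * (t[mask] - on))
    else:  # arhythmic control: participant-specific chained cycles
        if arhythmic_chain is None:
            raise ValueError("control group needs an arhythmic chain")
        on = ENTRAIN_ONSET
        idx = np.round((t - on) * chain_rate).astype(int)
        mask = (idx >= 0) & (idx < arhythmic_chain.size)
        drive[mask] = arhythmic_chain[idx[mask]]
    on_mask = drive != 0
    ramp = 1.0 - np.exp(
        -np.maximum(t - ENTRAIN_ONSET, 0.0) / config.entrain_ramp_tau
    )
    drive[on_mask] *= ramp[on_mask]
    return config.entrain_amplitude * drive


def _evoked_transient(config: CohortConfig, t: np.ndarray) -> np.ndarray:
    """Damped post-onset oscillation at the occipital peak."""
    resp = np.zeros_like(t)
    mask = t >= 0
    tt = t[mask]
    resp[mask] = np.exp(-tt / 0.3) * np.sin(2.0 * np.pi * 8.0 * tt)
    return config.evoked_amplitude * resp


def _participant_chain(config: CohortConfig, rng: np.random.Generator,
                       chain_rate: float = 1000.0) -> np.ndarray:
    """Zero-mean arhythmic luminance drive sampled at ``chain_rate`` Hz."""
    wf = make_arhythmic_waveform(
        target_duration_s=2.0, rng=rng, frame_rate=chain_rate
    )
    return 2.0 * (wf.frame_values - 0.5)  # map [0,1] -> [-1,1], zero-mean-ish


def simulate_eeg_trial(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    arhythmic_chain: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One trial segment, channels x samples, spanning -3.4 s ... +2.5 s."""
    if group not in VALID_GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if group == "control" and arhythmic_chain is None:
        arhythmic_chain = _participant_chain(config, rng)
    sfreq = config.sampling_rate
    n_samples = int(round((TRIAL_T_END - TRIAL_T_START) * sfreq))
    t = TRIAL_T_START + np.arange(n_samples) / sfreq
    ch = config.channel_labels
    w = _channel_weights(ch)
    seg = pink_noise(rng, len(ch), n_samples, sfreq,
                     config.noise_exponent, config.noise_std)
    phase = rng.uniform(0, 2 * np.pi)
    alpha = config.alpha_amplitude * np.sin(
        2 * np.pi * config.alpha_freq * t + phase
    )
    seg += np.outer(np.maximum(w, 0.1), alpha)
    drive = _entrain_drive(config, group, t, arhythmic_chain)
    seg += np.outer(w, drive + _evoked_transient(config, t))
    return seg


def simulate_eeg_epochs(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    n_trials: Optional[int] = None,
    inject: bool = False,
) -> tuple[EpochSet, list]:
    """Stack of simulated trial segments as an EpochSet.

    Faster than building a continuous recording when only epoched analyses
    are needed.  Returns the epochs and the artifact injection log.
    """
    if n_trials is None:
        n_trials = config.runs * config.encoding_trials_per_run
    chain = (_participant_chain(config, rng) if group == "control" else None)
    log: list = []
    trials = []
    for i in range(n_trials):
        seg = simulate_eeg_trial(config, group, rng, arhythmic_chain=chain)
        if inject:
            seg, entries = inject_artifacts(
                seg, config.artifact_rates, rng,
                sfreq=config.sampling_rate, ch_names=config.channel_labels,
            )
            for e in entries:
                e["trial"] = i
            log.extend(entries)
        trials.append(seg.astype(np.float32))
    data = np.stack(trials) if trials else np.empty(
        (0, len(config.channel_labels),
         int(round((TRIAL_T_END - TRIAL_T_START) * config.sampling_rate)))
    )
    meta = pd.DataFrame({"trial": np.arange(n_trials), "group": group})
    epochs = EpochSet(
        data=data.astype(float), sfreq=config.sampling_rate,
        t_start=TRIAL_T_START, t_end=TRIAL_T_END,
        ch_names=list(config.channel_labels), metadata=meta,
    )
    return epochs, log


def simulate_participant_eeg(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    n_trials: Optional[int] = None,
    inject: bool = True,
) -> tuple[Recording, list]:
    """Continuous recording with entrain/stim markers for one participant.

    The background (1/f noise and ongoing alpha) is continuous across the
    whole recording; trial-locked components are added around each onset.
    """
    if group not in VALID_GROUPS:
        raise ValueError(f"unknown group {group!r}")
    sfreq = config.sampling_rate
    if n_trials is None:
        n_trials = config.runs * config.encoding_trials_per_run
    spacing = config.trial_spacing_s
    margin = 5.0
    total_s = 2 * margin + n_trials * spacing
    n_samples = int(round(total_s * sfreq))
    ch = config.channel_labels
    w = _channel_weights(ch)
    data = pink_noise(rng, len(ch), n_samples, sfreq,
                      config.noise_exponent, config.noise_std)
    t_abs = np.arange(n_samples) / sfreq
    phase = rng.uniform(0, 2 * np.pi)
    alpha = config.alpha_amplitude * np.sin(
        2 * np.pi * config.alpha_freq * t_abs + phase
    )
    data += np.outer(np.maximum(w, 0.1), alpha)

    chain = (_participant_chain(config, rng) if group == "control" else None)
    onsets = (margin - TRIAL_T_START + spacing * np.arange(n_trials))
    onset_samples = np.round(onsets * sfreq).astype(int)
    seg_len = int(round((TRIAL_T_END - TRIAL_T_START) * sfreq))
    t_rel = TRIAL_T_START + np.arange(seg_len) / sfreq
    log: list = []
    events = []
    for i, onset in enumerate(onset_samples):
        start = onset + int(round(TRIAL_T_START * sfreq))
        drive = _entrain_drive(config, group, t_rel, chain)
        comp = np.outer(w, drive + _evoked_transient(config, t_rel))
        if inject:
            comp, entries = inject_artifacts(
                comp, config.artifact_rates, rng, sfreq=sfreq, ch_names=ch
            )
            for e in entries:
                e["trial"] = i
            log.extend(entries)
        data[:, start:start + seg_len] += comp
        events.append({"sample": int(onset + round(ENTRAIN_ONSET * sfreq)),
                       "code": "entrain_onset"})
        events.append({"sample": int(onset), "code": "stim_onset"})
    rec = Recording(
        data=data, sfreq=sfreq, ch_names=list(ch),
        events=pd.DataFrame(events).sort_values("sample").reset_index(drop=True),
    )
    return rec, log


def inject_artifacts(
    segment: np.ndarray,
    artifact_rates: dict,
    rng: np.random.Generator,
    sfreq: float = 500.0,
    ch_names: Optional[list] = None,
    jump_amplitude: float = 500.0,
    muscle_amplitude: float = 60.0,
    blink_amplitude: float = 200.0,
) -> tuple[np.ndarray, list]:
    """Superimpose step / high-frequency burst / blink artifacts.

    Each artifact type is injected independently with its stated
    probability; the log records type, channel and latency (samples).
    """
    seg = np.array(segment, dtype=float, copy=True)
    n_ch, n_samp = seg.shape
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(n_ch)]
    log = []
    rates = {"jump": 0.0, "muscle": 0.0, "blink": 0.0, **(artifact_rates or {})}

    if rng.uniform() < rates["jump"]:
        c = int(rng.integers(n_ch))
        at = int(rng.integers(n_samp // 10, 9 * n_samp // 10))
        seg[c, at:] += jump_amplitude * (1 if rng.uniform() < 0.5 else -1)
        log.append({"type": "jump", "channel": ch_names[c], "sample": at})

    if rng.uniform() < rates["muscle"]:
        # phasic EMG contaminates a patch of electrodes, not a single one
        width = min(8, n_ch)
        c0 = int(rng.integers(n_ch - width + 1))
        at = int(rng.integers(n_samp // 10, 8 * n_samp // 10))
        dur = int(0.3 * sfreq)
        tt = np.arange(dur) / sfreq
        burst = muscle_amplitude * np.sin(2 * np.pi * 35.0 * tt)
        burst *= np.hanning(dur)
        burst = burst[: max(0, n_samp - at)][: dur]
        for c in range(c0, c0 + width):
            seg[c, at:at + burst.size] += burst * rng.uniform(0.6, 1.0)
        log.append({"type": "muscle",
                    "channel": f"{ch_names[c0]}..{ch_names[c0 + width - 1]}",
                    "sample": at})

    if rng.uniform() < rates["blink"]:
        frontal = [i for i, ch in enumerate(ch_names)
                   if ch.startswith(("Fp", "AF", "EOG"))] or [0]
        at = int(rng.integers(n_samp // 10, 8 * n_samp // 10))
        dur = int(0.4 * sfreq)
        shape = blink_amplitude * np.hanning(dur)
        for c in frontal:
            seg[c, at:at + dur] += shape[: max(0, n_samp - at)][: dur]
        log.append({"type": "blink", "channel": "frontal", "sample": at})
    return seg, log


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero (d' cannot be negative)."""
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))


def simulate_behavior(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    dprime: Optional[float] = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-trial recognition table from an equal-variance SDT model.

    The participant's d' is drawn from the group's Normal(M, SD) truncated
    at 0 (unless given).  Old pairs generate familiarity ~ Normal(d', 1),
    recombined pairs ~ Normal(0, 1); the response is "old" when familiarity
    exceeds the criterion c.  A small fraction of trials is marked as
    missed responses (no button press within the 3 s window).
    """
    if group not in VALID_GROUPS:
        raise ValueError(f"unknown group {group!r}")
    m, sd = config.dprime_mean_sd_per_group[group]
    if dprime is None:
        dprime = _truncated_normal(rng, m, sd)
    c = config.criterion_c
    rows = []
    for run in range(config.runs):
        n_enc = config.encoding_trials_per_run
        status = np.array(["old"] * n_enc + ["new"] * n_enc)
        perm = rng.permutation(2 * n_enc)
        status = status[perm]
        fam = np.where(
            status == "old",
            rng.normal(dprime, 1.0, size=2 * n_enc),
            rng.normal(0.0, 1.0, size=2 * n_enc),
        )
        resp = np.where(fam > c, "old", "new")
        missed = rng.uniform(size=2 * n_enc) < config.p_missed
        resp = np.where(missed, "missed", resp)
        rt = config.rt_shift_s + rng.lognormal(
            config.rt_mu, config.rt_sigma, size=2 * n_enc
        )
        rt = np.where(missed, np.nan, np.minimum(rt, 3.0))
        for i in range(2 * n_enc):
            rows.append({
                "run": run, "trial": i, "status": status[i],
                "response": resp[i], "rt_ms": float(rt[i] * 1000.0)
                if np.isfinite(rt[i]) else np.nan,
            })
    table = pd.DataFrame(rows)
    truth = {"true_dprime": dprime, "criterion_c": c, "group": group}
    return table, truth


def simulate_participant(
    config: CohortConfig,
    group: str,
    participant_id: str,
    seed_seq: np.random.SeedSequence,
    n_trials: Optional[int] = None,
    with_eeg: bool = True,
) -> SimulatedParticipant:
    """Full simulated participant: continuous EEG + behaviour + ground truth."""
    eeg_ss, beh_ss = seed_seq.spawn(2)
    log: list = []
    if with_eeg:
        rec, log = simulate_participant_eeg(
            config, group, np.random.default_rng(eeg_ss), n_trials=n_trials
        )
    else:
        rec = Recording(
            data=np.zeros((len(config.channel_labels), 1)),
            sfreq=config.sampling_rate,
            ch_names=list(config.channel_labels),
        )
    behavior, truth = simulate_behavior(
        config, group, np.random.default_rng(beh_ss)
    )
    truth["artifact_log"] = log
    return SimulatedParticipant(
        participant_id=participant_id, group=group,
        eeg=rec, behavior=behavior, truth=truth,
    )


def simulate_cohort_behavior(
    config: CohortConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Behaviour tables for a whole cohort, one row per trial."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    for group in config.groups:
        k = config.k_per_group if group != "ne" else config.ne_pool_k
        for p in range(k):
            table, truth = simulate_behavior(config, group, rng)
            table.insert(0, "participant", f"{group}_{p:03d}")
            table.insert(1, "group", group)
            table["true_dprime"] = truth["true_dprime"]
            frames.append(table)
    return pd.concat(frames, ignore_index=True)
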
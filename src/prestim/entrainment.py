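"""Entrainment-success criterion, strength, and spectral-peak analyses.

Entrainment is judged on the percent-change time-frequency volume,
averaged over the occipital channels O1/O2/Oz and the stimulation band
(centre +/- 1 Hz): the late stimulation window (-1.1 to -0.1 s) must show
at least +10% relative power for at least 500 ms.  Individual alpha and
theta frequencies (IAF/ITF) are the resting-spectrum power maxima in
8-12 / 3-7 Hz over posterior electrodes; their distance to the stimulation
frequency can be correlated with entrainment strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .timefreq import PowerSpectrum, TFRVolume

CRITERION_CHANNELS = ("O1", "O2", "Oz")
#: Posterior electrode set used for IAF/ITF extraction.
PEAK_ELECTRODES = ("Pz", "POz", "Oz", "O1", "O2", "P3", "P4", "PO3", "PO4")
ALPHA_BAND = (8.0, 12.0)
THETA_BAND = (3.0, 7.0)
LATE_WINDOW = (-1.1, -0.1)


@dataclass
class EntrainmentAssessment:
    participant_id: str
    stim_freq: float
    window: tuple
    timecourse: np.ndarray
    times: np.ndarray
    max_percent_change: float
    sustained_ms: float
    passed: bool
    threshold: float
    min_duration_ms: float


@dataclass
class SpectralPeak:
    kind: str  # "IAF" | "ITF"
    band: tuple
    electrodes: tuple
    peak_frequency_hz: float
    distance_to_stim_hz: float
    tied: bool = False


def assess_entrainment(
    tfr: TFRVolume,
    stim_freq: float,
    threshold: float = 10.0,
    min_duration_ms: float = 500.0,
    window: tuple = LATE_WINDOW,
    channels: Sequence[str] = CRITERION_CHANNELS,
    participant_id: str = "",
) -> EntrainmentAssessment:
    """Apply the 10% / 500 ms criterion to a percent-change volume.

    The timecourse is the percent change averaged over ``channels`` and the
    three band bins (stim_freq +/- 1 Hz).  With a 100 ms decomposition
    step, "at least 500 ms" means at least 5 contiguous time bins at or
    above threshold; the window's bins are taken left-inclusive
    (t in [-1.1, -0.1)) so a full-window pass sustains exactly 1000 ms.
    """
    if tfr.baseline_mode != "percent_change":
        raise ValueError("assessment requires a percent-change volume")
    vol = tfr.trial_average()
    ch_idx = vol.channel_indices(channels)
    band = (vol.freqs >= stim_freq - 1 - 1e-9) & \
           (vol.freqs <= stim_freq + 1 + 1e-9)
    if band.sum() < 1:
        raise ValueError("stimulation band outside the frequency grid")
    t0, t1 = window
    in_win = (vol.times >= t0 - 1e-9) & (vol.times < t1 - 1e-9)
    tc = vol.power[np.ix_(ch_idx, np.flatnonzero(band),
                          np.flatnonzero(in_win))].mean(axis=(0, 1))
    step_ms = float(np.median(np.diff(vol.times))) * 1000.0
    above = tc >= threshold
    longest = run = 0
    for a in above:
        run = run + 1 if a else 0
        longest = max(longest, run)
    sustained_ms = longest * step_ms
    passed = sustained_ms >= min_duration_ms
    return EntrainmentAssessment(
        participant_id=participant_id, stim_freq=stim_freq, window=window,
        timecourse=tc, times=vol.times[in_win],
        max_percent_change=float(tc.max()) if tc.size else float("nan"),
        sustained_ms=float(sustained_ms), passed=bool(passed),
        threshold=threshold, min_duration_ms=min_duration_ms,
    )


def extract_band_peak(
    spectrum: PowerSpectrum,
    band: tuple,
    electrodes: Sequence[str] = PEAK_ELECTRODES,
    stim_freq: Optional[float] = None,
    kind: str = "IAF",
) -> SpectralPeak:
    """Frequency of maximum electrode-averaged power within a band.

    Ties are broken toward the lower frequency and flagged with a warning.
    """
    missing = [e for e in electrodes if e not in spectrum.ch_names]
    if missing:
        raise KeyError(f"electrodes not present: {missing}")
    idx = [spectrum.ch_names.index(e) for e in electrodes]
    in_band = (spectrum.freqs >= band[0] - 1e-9) & \
              (spectrum.freqs <= band[1] + 1e-9)
    if not in_band.any():
        raise ValueError("band outside the frequency grid")
    mean_pow = spectrum.power[idx][:, in_band].mean(axis=0)
    band_freqs = spectrum.freqs[in_band]
    best = int(np.argmax(mean_pow))
    tied = bool(np.sum(np.isclose(mean_pow, mean_pow[best], rtol=1e-12,
                                  atol=0)) > 1)
    if tied:
        warnings.warn(
            f"{kind} peak tied within {band}; lower frequency returned",
            stacklevel=2,
        )
    peak = float(band_freqs[best])
    distance = abs(peak - stim_freq) if stim_freq is not None else np.nan
    return SpectralPeak(
        kind=kind, band=band, electrodes=tuple(electrodes),
        peak_frequency_hz=peak, distance_to_stim_hz=float(distance),
        tied=tied,
    )


def distance_strength_correlation(
    distances: np.ndarray, strengths: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of peak distance vs strength."""
    distances = np.asarray(distances, dtype=float)
    strengths = np.asarray(strengths, dtype=float)
    if distances.shape != strengths.shape or distances.size < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.isfinite(distances).all() and np.isfinite(strengths).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(distances) == 0 or np.ptp(strengths) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(distances, strengths)
    return float(r), float(p)
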
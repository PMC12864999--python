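"""Time-frequency decomposition, baseline normalisation, resting spectra.

The trial decomposition is a sliding-window Fourier transform with a fixed
500 ms Hanning taper stepped every 100 ms, evaluated at integer frequencies
1-40 Hz (the taper length, not cycles per frequency, sets the spectral
resolution).  Power is expressed as percent change relative to the
pre-stimulation baseline (-3.1 to -2.1 s).  Resting-state spectra use a
multitaper FFT with +/-2 Hz smoothing on 2-s epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal.windows import dpss

from .containers import EpochSet

DEFAULT_FREQS = np.arange(1, 41, dtype=float)
DEFAULT_TFR_TIMES = np.round(np.arange(-3.1, 2.2001, 0.1), 10)
BASELINE_WINDOW = (-3.1, -2.1)


@dataclass
class TFRVolume:
    """channels x frequencies x times power array (optionally per trial).

    ``power`` has shape (n_channels, n_freqs, n_times) when trial-averaged
    or (n_trials, n_channels, n_freqs, n_times) otherwise, in uV^2 for
    ``baseline_mode="raw"`` or percent for ``baseline_mode="percent_change"``.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ch_names: list
    baseline_mode: str = "raw"
    baseline_window: tuple = BASELINE_WINDOW

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.baseline_mode == "raw" and (self.power < -1e-12).any():
            raise ValueError("raw power must be non-negative")

    @property
    def is_trialwise(self) -> bool:
        return self.power.ndim == 4

    def trial_average(self) -> "TFRVolume":
        if not self.is_trialwise:
            return self
        return TFRVolume(
            power=self.power.mean(axis=0), freqs=self.freqs,
            times=self.times, ch_names=list(self.ch_names),
            baseline_mode=self.baseline_mode,
            baseline_window=self.baseline_window,
        )

    def channel_indices(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.ch_names]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return np.array([self.ch_names.index(n) for n in names])


@dataclass
class PowerSpectrum:
    """channels x frequencies multitaper power (uV^2), integer-Hz grid."""

    power: np.ndarray
    freqs: np.ndarray
    ch_names: list
    method: str = "multitaper"
    smoothing_hz: float = 2.0
    n_epochs_averaged: int = 0

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if (self.power < -1e-12).any():
            raise ValueError("power must be non-negative")


def tfr_hanning(
    epochs: EpochSet,
    window_len: float = 0.5,
    step: float = 0.1,
    freqs: np.ndarray = DEFAULT_FREQS,
    times: Optional[np.ndarray] = None,
    average: bool = True,
) -> TFRVolume:
    """Sliding Hanning-taper Fourier power at the requested times/frequencies.

    Epoch samples outside the output time range act as padding; requesting
    an output time whose window is not fully covered by the epoch raises.
    """
    sfreq = epochs.sfreq
    if times is None:
        times = DEFAULT_TFR_TIMES
    times = np.asarray(times, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    n_win = int(round(window_len * sfreq))
    taper = np.hanning(n_win)
    half = n_win // 2
    epoch_times = epochs.times
    # start sample of the window centred at each output time
    centers = np.round((times - epochs.t_start) * sfreq).astype(int)
    starts = centers - half
    if starts.min() < 0 or (starts + n_win).max() > epochs.data.shape[2]:
        raise ValueError(
            "requested times need windows outside the available data "
            f"(epoch covers {epoch_times[0]:.3f}..{epoch_times[-1]:.3f} s)"
        )
    # complex exponential basis, taper folded in: (n_freqs, n_win)
    tau = np.arange(n_win) / sfreq
    basis = taper * np.exp(-2j * np.pi * freqs[:, None] * tau[None, :])
    # windows: (n_trials, n_ch, n_times, n_win) via stride gather
    idx = starts[:, None] + np.arange(n_win)[None, :]
    windows = epochs.data[:, :, idx]  # (trials, ch, times, win)
    spec = np.tensordot(windows, basis, axes=([3], [1]))  # trials,ch,times,freq
    power = (spec.real ** 2 + spec.imag ** 2)
    # normalise so a unit-amplitude sinusoid has taper-independent scale
    norm = (taper ** 2).sum() * sfreq / 2.0
    power = power / norm
    power = np.moveaxis(power, 3, 2)  # trials, ch, freqs, times
    if average:
        power = power.mean(axis=0)
    return TFRVolume(
        power=power, freqs=freqs, times=times, ch_names=list(epochs.ch_names),
        baseline_mode="raw",
    )


def baseline_percent_change(
    tfr: TFRVolume, baseline: tuple = BASELINE_WINDOW
) -> TFRVolume:
    """100 * (P - B) / B with B the baseline-window mean of trial-averaged power."""
    if tfr.baseline_mode != "raw":
        raise ValueError("input volume is already baseline-normalised")
    t0, t1 = baseline
    in_base = (tfr.times >= t0 - 1e-9) & (tfr.times <= t1 + 1e-9)
    if not in_base.any():
        raise ValueError("baseline window outside the time axis")
    avg = tfr.trial_average().power  # (ch, f, t)
    b = avg[:, :, in_base].mean(axis=2)  # (ch, f)
    bad = np.argwhere(b <= 0)
    if bad.size:
        ch_i, f_i = bad[0]
        raise ValueError(
            f"zero baseline power at channel {tfr.ch_names[ch_i]}, "
            f"{tfr.freqs[f_i]:g} Hz"
        )
    if tfr.is_trialwise:
        pc = 100.0 * (tfr.power - b[None, :, :, None]) / b[None, :, :, None]
    else:
        pc = 100.0 * (tfr.power - b[:, :, None]) / b[:, :, None]
    return TFRVolume(
        power=pc, freqs=tfr.freqs, times=tfr.times,
        ch_names=list(tfr.ch_names), baseline_mode="percent_change",
        baseline_window=baseline,
    )


def resting_spectrum(
    epochs: EpochSet,
    smoothing_hz: float = 2.0,
    freqs: np.ndarray = DEFAULT_FREQS,
) -> PowerSpectrum:
    """Subject-level multitaper spectrum from resting 2-s epochs.

    DPSS tapers with time-bandwidth product T * W (W = ``smoothing_hz``)
    are applied per epoch; power is averaged over tapers and clean epochs.
    """
    kept = epochs.kept()
    if kept.n_trials < 1:
        raise ValueError("no clean epochs to average")
    freqs = np.asarray(freqs, dtype=float)
    n_samp = kept.data.shape[2]
    sfreq = kept.sfreq
    t_len = n_samp / sfreq
    nw = max(t_len * smoothing_hz, 1.0)
    k = max(int(2 * nw - 1), 1)
    tapers = dpss(n_samp, nw, Kmax=k)  # (k, n_samp)
    fft_freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    bins = np.array([np.argmin(np.abs(fft_freqs - f)) for f in freqs])
    # (trials, ch, k, n_samp) -> rfft -> power
    tapered = kept.data[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(tapered, axis=3)[..., bins]
    power = (spec.real ** 2 + spec.imag ** 2).mean(axis=(0, 2))
    power /= sfreq * n_samp / 2.0
    return PowerSpectrum(
        power=power, freqs=freqs, ch_names=list(kept.ch_names),
        smoothing_hz=smoothing_hz, n_epochs_averaged=kept.n_trials,
    )


def make_resting_epochs(
    recording, trim_s: float = 15.0, epoch_len_s: float = 2.0
) -> EpochSet:
    """Split a resting recording into consecutive epochs, edges trimmed.

    A 3.5-minute recording trimmed by 15 s at each end yields ninety 2-s
    epochs.
    """
    sfreq = recording.sfreq
    start = int(round(trim_s * sfreq))
    stop = recording.n_samples - start
    seg = recording.data[:, start:stop]
    n_per = int(round(epoch_len_s * sfreq))
    n_epochs = seg.shape[1] // n_per
    data = np.stack(
        [seg[:, i * n_per:(i + 1) * n_per] for i in range(n_epochs)]
    )
    return EpochSet(
        data=data, sfreq=sfreq, t_start=0.0, t_end=epoch_len_s,
        ch_names=list(recording.ch_names),
    )
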
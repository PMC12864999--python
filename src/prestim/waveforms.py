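"""Luminance modulation waveforms for pre-stimulus visual entrainment.

Rhythmic stimulation modulates the luminance of a fixed image as a raised
cosine at the target frequency (5 Hz theta, 9 Hz alpha), sampled at the
monitor frame rate.  The arhythmic control chains complete single cycles
whose frequencies are drawn from 13-24 Hz, excluding the harmonics of the
two stimulation frequencies (15, 18, 20 Hz).  Every waveform starts and
ends at zero luminance (image invisible), and stimulation is followed by a
dark gap of half a stimulation cycle before stimulus onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Monitor refresh rate used for stimulation (frames per second).
DEFAULT_FRAME_RATE = 240.0

#: Integer cycle frequencies allowed in the arhythmic control waveform.
#: 15, 18 and 20 Hz are excluded as harmonics of the 5 and 9 Hz stimulation.
ARHYTHMIC_POOL = (13, 14, 16, 17, 19, 21, 22, 23, 24)

_FORBIDDEN_HARMONICS = frozenset({15, 18, 20})


@dataclass
class LuminanceWaveform:
    """A sampled luminance modulation in [0, 1] at the monitor frame rate."""

    frame_values: np.ndarray
    frame_rate: float
    kind: str  # "rhythmic" | "arhythmic"
    duration_s: float
    gap_ms: float
    frequency_hz: Optional[float] = None
    cycle_frequencies_hz: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.frame_values = np.asarray(self.frame_values, dtype=float)
        if self.frame_values.size:
            if not (self.frame_values >= -1e-12).all() or not (
                self.frame_values <= 1 + 1e-12
            ).all():
                raise ValueError("luminance values must lie in [0, 1]")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.frame_values.size) / self.frame_rate

    def to_tsv(self, path) -> None:
        arr = np.column_stack([self.times_s, self.frame_values])
        np.savetxt(path, arr, delimiter="\t", header="time_s\tluminance",
                   comments="")

    def metadata(self) -> dict:
        meta = {
            "kind": self.kind,
            "frame_rate": self.frame_rate,
            "duration_s": self.duration_s,
            "gap_ms": self.gap_ms,
            "seed": self.seed,
        }
        if self.kind == "rhythmic":
            meta["frequency_hz"] = self.frequency_hz
        else:
            meta["cycle_frequencies_hz"] = [
                float(f) for f in self.cycle_frequencies_hz
            ]
        return meta

    def metadata_json(self) -> str:
        return json.dumps(self.metadata())


def make_rhythmic_waveform(
    frequency_hz: float,
    duration_s: float = 2.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> LuminanceWaveform:
    """Raised-cosine luminance L(t) = (1 - cos(2*pi*f*t)) / 2.

    The modulation starts and ends dark, peaks at full luminance once per
    cycle, and must span an integer number of cycles so the gap that follows
    continues the rhythm coherently.
    """
    if frequency_hz <= 0:
        raise ValueError("frequency_hz must be positive")
    n_cycles = duration_s * frequency_hz
    if abs(n_cycles - round(n_cycles)) > 1e-9:
        raise ValueError(
            f"duration_s * frequency_hz = {n_cycles} is not an integer "
            "number of cycles"
        )
    if frame_rate < 2 * frequency_hz:
        raise ValueError("frame_rate must be at least twice the frequency")
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) / frame_rate
    values = (1.0 - np.cos(2.0 * np.pi * frequency_hz * t)) / 2.0
    # The cycle completes exactly at t = duration_s, one frame interval past
    # the final sample; that frame is dark anyway (the gap), so the last
    # displayed frame is forced dark to honour the start/end-at-zero contract.
    values[-1] = 0.0
    values[0] = 0.0
    return LuminanceWaveform(
        frame_values=values,
        frame_rate=frame_rate,
        kind="rhythmic",
        duration_s=duration_s,
        gap_ms=post_stimulation_gap(frequency_hz),
        frequency_hz=frequency_hz,
    )


def make_arhythmic_waveform(
    target_duration_s: float = 2.0,
    frequency_pool: Sequence[int] = ARHYTHMIC_POOL,
    rng: Optional[np.random.Generator] = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
    seed: Optional[int] = None,
) -> LuminanceWaveform:
    """Chain complete single raised-cosine cycles of random frequencies.

    Cycle frequencies are drawn uniformly from ``frequency_pool``.  Chaining
    is greedy: cycles are appended as long as the total duration stays within
    ``target_duration_s``; the first draw that would overflow stops the
    chain.  Each cycle starts and ends at zero luminance so the chain is
    continuous.
    """
    pool = np.asarray(frequency_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("frequency_pool is empty")
    if any(int(f) in _FORBIDDEN_HARMONICS for f in pool):
        raise ValueError(
            "frequency_pool must not contain the stimulation harmonics "
            "15, 18 or 20 Hz"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    drawn: list[float] = []
    total = 0.0
    while True:
        f = float(rng.choice(pool))
        if total + 1.0 / f > target_duration_s + 1e-12:
            break
        drawn.append(f)
        total += 1.0 / f

    # Sample the chain at the frame rate: within cycle i of frequency f_i,
    # L(t) = (1 - cos(2*pi*f_i*(t - t_i)))/2 with t_i the cycle start.
    n_frames = int(np.floor(total * frame_rate)) + 1
    t = np.arange(n_frames) / frame_rate
    values = np.zeros(n_frames)
    starts = np.concatenate([[0.0], np.cumsum(1.0 / np.array(drawn))])
    for f, t0, t1 in zip(drawn, starts[:-1], starts[1:]):
        mask = (t >= t0 - 1e-12) & (t < t1 - 1e-12)
        values[mask] = (1.0 - np.cos(2.0 * np.pi * f * (t[mask] - t0))) / 2.0
    if n_frames:
        values[0] = 0.0
        values[-1] = 0.0
    return LuminanceWaveform(
        frame_values=values,
        frame_rate=frame_rate,
        kind="arhythmic",
        duration_s=total,
        gap_ms=post_stimulation_gap(arhythmic=True),
        cycle_frequencies_hz=np.array(drawn),
        seed=seed,
    )


def post_stimulation_gap(
    frequency_hz: Optional[float] = None, arhythmic: bool = False
) -> float:
    """Dark interval (ms) between waveform end and stimulus onset.

    Half a stimulation cycle for rhythmic groups (100 ms at 5 Hz, 56 ms at
    9 Hz, rounded to integer milliseconds); a fixed 50 ms for the arhythmic
    control.
    """
    if arhythmic:
        return 50.0
    if frequency_hz is None or frequency_hz <= 0:
        raise ValueError("frequency_hz must be positive for rhythmic gaps")
    return float(round(1000.0 / (2.0 * frequency_hz)))


def arhythmic_duration_stats(
    n_waveforms: int = 10_000,
    target_duration_s: float = 2.0,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Monte-Carlo mean and SD of arhythmic waveform durations.

    Uses the chaining rule directly (no frame sampling) so large simulation
    counts run in well under a second.
    """
    rng = np.random.default_rng(seed)
    pool = np.asarray(ARHYTHMIC_POOL, dtype=float)
    durations = np.empty(n_waveforms)
    # Draw in blocks: the chain needs at most ceil(target * max_f) cycles.
    max_cycles = int(np.ceil(target_duration_s * pool.max())) + 1
    draws = rng.choice(pool, size=(n_waveforms, max_cycles))
    cyc = np.cumsum(1.0 / draws, axis=1)
    for i in range(n_waveforms):
        over = np.searchsorted(cyc[i], target_duration_s + 1e-12)
        durations[i] = cyc[i, over - 1] if over > 0 else 0.0
    return float(durations.mean()), float(durations.std(ddof=1))
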
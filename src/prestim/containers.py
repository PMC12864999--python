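"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """Continuous multichannel EEG with event markers.

    data : (n_channels, n_samples) float array, microvolts
    sfreq : sampling rate in Hz
    ch_names : channel labels (10-20 names plus EOG)
    events : DataFrame with columns ``sample`` (int) and ``code`` (str);
        codes used by the pipeline are ``entrain_onset`` and ``stim_onset``.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "code"])
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match data rows")
        if len(self.events):
            samples = self.events["sample"].to_numpy()
            if (np.diff(samples) < 0).any():
                raise ValueError("event samples must be non-decreasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def event_samples(self, code: str) -> np.ndarray:
        return self.events.loc[
            self.events["code"] == code, "sample"
        ].to_numpy(dtype=int)


@dataclass
class EpochSet:
    """Trials x channels x samples tensor with per-trial metadata.

    The time axis runs from ``t_start`` to ``t_end`` (seconds relative to
    stimulus onset); sample ``-t_start * sfreq`` is the onset sample.
    ``rejected`` holds ``None`` for retained trials or a single reason tag
    (``jump`` | ``muscle`` | ``edge`` | ``user``).
    """

    data: np.ndarray
    sfreq: float
    t_start: float
    t_end: float
    ch_names: list[str]
    metadata: Optional[pd.DataFrame] = None
    rejected: list = field(default_factory=list)
    rejection_scores: Optional[pd.DataFrame] = None

    VALID_REASONS = ("jump", "muscle", "edge", "user")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_expected = int(round((self.t_end - self.t_start) * self.sfreq))
        if self.data.shape[0] and self.data.shape[2] != n_expected:
            raise ValueError(
                f"time axis has {self.data.shape[2]} samples, expected "
                f"{n_expected} for [{self.t_start}, {self.t_end}) at "
                f"{self.sfreq} Hz"
            )
        if not self.rejected:
            self.rejected = [None] * self.data.shape[0]
        for r in self.rejected:
            if r is not None and r not in self.VALID_REASONS:
                raise ValueError(f"unknown rejection reason {r!r}")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.data.shape[2]) / self.sfreq

    @property
    def kept_mask(self) -> np.ndarray:
        return np.array([r is None for r in self.rejected])

    def kept(self) -> "EpochSet":
        """Return a copy containing only non-rejected trials."""
        mask = self.kept_mask
        meta = self.metadata.loc[mask].reset_index(drop=True) \
            if self.metadata is not None else None
        return EpochSet(
            data=self.data[mask],
            sfreq=self.sfreq,
            t_start=self.t_start,
            t_end=self.t_end,
            ch_names=list(self.ch_names),
            metadata=meta,
            rejected=[None] * int(mask.sum()),
        )

    def channel_indices(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.ch_names]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return np.array([self.ch_names.index(n) for n in names])

    def rejection_log(self) -> pd.DataFrame:
        rows = [
            {"trial": i, "reason": r}
            for i, r in enumerate(self.rejected)
            if r is not None
        ]
        return pd.DataFrame(rows, columns=["trial", "reason"])
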
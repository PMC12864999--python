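"""Signal-detection scoring of recognition behaviour.

Four outcomes are counted per participant — hits (old pairs called old),
misses, correct rejections, and false alarms (new pairs called old) —
pooled over runs; trials without a button press inside the response
window are tallied separately and excluded from the rate denominators.
Sensitivity is d' = z(hit rate) - z(false-alarm rate) under the
equal-variance model, with a boundary-only log-linear rate correction so
the z-transform stays finite.  Participants with a false-alarm rate above
25% are excluded from inference.  The no-entrainment comparison cohort is
reduced to the entrainment group size by drawing 50 random subsamples and
keeping the one whose mean is closest to the full-sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

FA_EXCLUSION_THRESHOLD = 0.25


@dataclass
class SDTSummary:
    participant_id: str
    hits: int
    misses: int
    correct_rejections: int
    false_alarms: int
    missed_responses: int
    hit_rate: float
    fa_rate: float
    dprime: float
    excluded: bool
    exclusion_reason: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "participant": self.participant_id,
            "hits": self.hits, "misses": self.misses,
            "correct_rejections": self.correct_rejections,
            "false_alarms": self.false_alarms,
            "missed_responses": self.missed_responses,
            "hit_rate": self.hit_rate, "fa_rate": self.fa_rate,
            "dprime": self.dprime, "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
        }


def rate_correction(count: int, n: int) -> float:
    """Boundary-only log-linear correction: (c + 0.5) / (n + 1) at 0 or n."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    if count == 0 or count == n:
        return (count + 0.5) / (n + 1.0)
    return count / n


def score_recognition(
    trials: pd.DataFrame, participant_id: str = ""
) -> SDTSummary:
    """Count SDT outcomes and compute d' from one recognition table.

    ``trials`` needs columns ``status`` (old|new) and ``response``
    (old|new|missed).  Rates are computed over valid (responded) trials,
    pooled across runs.
    """
    status = trials["status"].to_numpy()
    response = trials["response"].to_numpy()
    valid = response != "missed"
    missed = int((~valid).sum())
    old = status == "old"
    new = status == "new"
    hits = int((old & valid & (response == "old")).sum())
    misses = int((old & valid & (response == "new")).sum())
    fas = int((new & valid & (response == "old")).sum())
    crs = int((new & valid & (response == "new")).sum())
    n_old = hits + misses
    n_new = fas + crs
    if n_old == 0 or n_new == 0:
        raise ValueError("need at least one valid old and one valid new trial")
    hit_rate = rate_correction(hits, n_old)
    fa_rate = rate_correction(fas, n_new)
    dprime = float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))
    excluded = fa_rate > FA_EXCLUSION_THRESHOLD
    return SDTSummary(
        participant_id=participant_id,
        hits=hits, misses=misses, correct_rejections=crs, false_alarms=fas,
        missed_responses=missed, hit_rate=float(hit_rate),
        fa_rate=float(fa_rate), dprime=dprime, excluded=bool(excluded),
        exclusion_reason="fa_rate_above_25pct" if excluded else None,
    )


def score_cohort(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per-participant SDT table from a cohort behaviour table.

    Expects columns ``participant``, ``group``, ``status``, ``response``.
    """
    rows = []
    for (pid, group), sub in behavior.groupby(["participant", "group"],
                                              sort=False):
        summary = score_recognition(sub, participant_id=pid)
        d = summary.as_dict()
        d["group"] = group
        if "true_dprime" in sub.columns:
            d["true_dprime"] = float(sub["true_dprime"].iloc[0])
        rows.append(d)
    return pd.DataFrame(rows)


def encoding_accuracy(trials: pd.DataFrame) -> float:
    """Proportion of correct animal-categorization responses (descriptive)."""
    valid = trials["response"] != "missed"
    if valid.sum() == 0:
        return float("nan")
    return float((trials.loc[valid, "response"] ==
                  trials.loc[valid, "correct_response"]).mean())


@dataclass
class SubsampleMatch:
    indices: np.ndarray
    subsample_mean: float
    full_mean: float
    candidate_means: np.ndarray

    @property
    def mean_difference(self) -> float:
        return abs(self.subsample_mean - self.full_mean)


def ne_subsample_match(
    ne_scores: np.ndarray,
    target_k: int = 35,
    draws: int = 50,
    rng: Optional[np.random.Generator] = None,
) -> SubsampleMatch:
    """Mean-matched subsample of the larger no-entrainment cohort.

    Draws ``draws`` random size-``target_k`` subsamples without
    replacement and keeps the one whose mean is closest to the full-sample
    mean (ties broken by first occurrence).  All candidate means are
    recorded for provenance.
    """
    scores = np.asarray(ne_scores, dtype=float)
    if target_k > scores.size:
        raise ValueError("target_k exceeds the available sample size")
    if rng is None:
        rng = np.random.default_rng()
    full_mean = scores.mean()
    candidates = np.empty((draws, target_k), dtype=int)
    means = np.empty(draws)
    for i in range(draws):
        idx = rng.choice(scores.size, size=target_k, replace=False)
        candidates[i] = idx
        means[i] = scores[idx].mean()
    best = int(np.argmin(np.abs(means - full_mean)))
    return SubsampleMatch(
        indices=np.sort(candidates[best]),
        subsample_mean=float(means[best]),
        full_mean=float(full_mean),
        candidate_means=means,
    )
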
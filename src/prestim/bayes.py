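"""JZS (Cauchy-prior) Bayes factors and the sequential design monitor.

The default Bayesian two-sample t-test places a Cauchy(0, r) prior on the
standardized effect size delta (r = sqrt(2)/2, "medium" width) under H1
and a point mass at delta = 0 under H0.  With the pooled two-sample t
statistic, BF10 is the ratio of the marginal likelihood of t under the
prior (a noncentral-t mixture, integrated numerically) to the central-t
density.  One-sided variants truncate the prior to the predicted
half-line.  The sequential monitor re-evaluates the BF as group size
grows from k = 15, stopping at BF10 >= 3, BF10 <= 1/3, or k = 35.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, stats

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0
SIDEDNESS = ("two_sided", "one_sided_greater", "one_sided_less")


@dataclass
class BFResult:
    bf10: float
    t_stat: float
    df: int
    n1: int
    n2: int
    prior_scale: float
    sidedness: str

    def __post_init__(self) -> None:
        if not (self.bf10 > 0):
            raise ValueError("bf10 must be positive")


@dataclass
class SequentialState:
    contrast: str
    k_trace: list
    bf_trace: list
    thresholds: tuple = (3.0, 1.0 / 3.0)
    k_start: int = 15
    k_max: int = 35
    decision: str = "continuing"
    decided_at_k: Optional[int] = None


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Equal-variance two-sample t statistic and its degrees of freedom."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (mean1 - mean2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, df


def _jzs_bf_from_t(
    t: float, n1: int, n2: int, r: float, sidedness: str
) -> float:
    """Marginal-likelihood ratio by adaptive quadrature over delta."""
    df = n1 + n2 - 2
    n_eff = 1.0 / (1.0 / n1 + 1.0 / n2)
    sqrt_n = math.sqrt(n_eff)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * sqrt_n) * \
            stats.cauchy.pdf(delta, 0.0, r)

    h0 = stats.t.pdf(t, df)
    if h0 == 0:
        raise ValueError("degenerate likelihood at delta = 0")
    opts = {"limit": 200, "epsabs": 1e-12, "epsrel": 1e-10}
    if sidedness == "two_sided":
        lo, err_lo = integrate.quad(integrand, -np.inf, 0.0, **opts)
        hi, err_hi = integrate.quad(integrand, 0.0, np.inf, **opts)
        num, err = lo + hi, err_lo + err_hi
    elif sidedness == "one_sided_greater":
        num, err = integrate.quad(integrand, 0.0, np.inf, **opts)
        num, err = 2.0 * num, 2.0 * err  # truncated prior renormalisation
    elif sidedness == "one_sided_less":
        num, err = integrate.quad(integrand, -np.inf, 0.0, **opts)
        num, err = 2.0 * num, 2.0 * err
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if num <= 0 or not np.isfinite(num) or err > max(1e-6 * num, 1e-12):
        raise RuntimeError(
            f"quadrature failed (value={num}, abs err={err}); "
            "check the inputs"
        )
    return num / h0


def jzs_bf_two_sample(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    r: float = DEFAULT_PRIOR_SCALE,
    sidedness: str = "two_sided",
) -> BFResult:
    """JZS Bayes factor for a two-sample comparison from summary statistics.

    ``one_sided_greater`` predicts mean1 > mean2 (prior truncated to
    delta > 0).
    """
    for v in (mean1, sd1, mean2, sd2):
        if not np.isfinite(v):
            raise ValueError("summary statistics must be finite")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    t, df = pooled_t(mean1, sd1, n1, mean2, sd2, n2)
    bf10 = _jzs_bf_from_t(t, n1, n2, r, sidedness)
    return BFResult(
        bf10=float(bf10), t_stat=float(t), df=df, n1=n1, n2=n2,
        prior_scale=r, sidedness=sidedness,
    )


def jzs_bf_from_samples(
    x: np.ndarray, y: np.ndarray,
    r: float = DEFAULT_PRIOR_SCALE,
    sidedness: str = "two_sided",
) -> BFResult:
    """Raw-vector entry point; delegates to the summary-statistic form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return jzs_bf_two_sample(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
        r=r, sidedness=sidedness,
    )


def jzs_bf_grid_oracle(
    t: float, n1: int, n2: int,
    r: float = DEFAULT_PRIOR_SCALE,
    sidedness: str = "two_sided",
    delta_max: float = 30.0,
    n_grid: int = 200_001,
) -> float:
    """Independent dense-trapezoid evaluation of the same marginal likelihood.

    Deliberately naive (uniform grid over [-delta_max, delta_max]); serves
    as a cross-check for the adaptive quadrature, not for production use.
    """
    df = n1 + n2 - 2
    n_eff = 1.0 / (1.0 / n1 + 1.0 / n2)
    if sidedness == "one_sided_greater":
        delta = np.linspace(0.0, delta_max, n_grid)
        scale = 2.0
    elif sidedness == "one_sided_less":
        delta = np.linspace(-delta_max, 0.0, n_grid)
        scale = 2.0
    else:
        delta = np.linspace(-delta_max, delta_max, n_grid)
        scale = 1.0
    dens = stats.nct.pdf(t, df, delta * np.sqrt(n_eff)) * \
        stats.cauchy.pdf(delta, 0.0, r)
    num = scale * np.trapezoid(dens, delta)
    return float(num / stats.t.pdf(t, df))


def sequential_monitor(
    looks: Sequence[dict],
    contrast: str = "",
    thresholds: tuple = (3.0, 1.0 / 3.0),
    k_start: int = 15,
    k_max: int = 35,
    r: float = DEFAULT_PRIOR_SCALE,
    sidedness: str = "two_sided",
) -> SequentialState:
    """Open-ended sequential design: test at every added participant.

    ``looks`` is an ordered sequence of per-look group summaries, each a
    dict with keys ``k, mean1, sd1, mean2, sd2`` (equal group sizes per
    look).  Evaluation starts at ``k_start``; the trace stops at the first
    BF threshold crossing or at ``k_max``.
    """
    upper, lower = max(thresholds), min(thresholds)
    ks = [int(l["k"]) for l in looks]
    if ks and ks[0] != k_start:
        raise ValueError(f"first look must be at k = {k_start}, got {ks[0]}")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k_trace must increase contiguously by 1")
    state = SequentialState(
        contrast=contrast, k_trace=[], bf_trace=[],
        thresholds=(upper, lower), k_start=k_start, k_max=k_max,
    )
    for look in looks:
        k = int(look["k"])
        bf = jzs_bf_two_sample(
            look["mean1"], look["sd1"], k,
            look["mean2"], look["sd2"], k,
            r=r, sidedness=sidedness,
        ).bf10
        state.k_trace.append(k)
        state.bf_trace.append(bf)
        if bf >= upper:
            state.decision = "accept_H1"
            state.decided_at_k = k
            break
        if bf <= lower:
            state.decision = "accept_H0"
            state.decided_at_k = k
            break
        if k >= k_max:
            state.decision = "max_n_reached"
            state.decided_at_k = k
            break
    return state


def looks_from_scores(
    scores1: np.ndarray, scores2: np.ndarray, k_start: int = 15
) -> list[dict]:
    """Build per-look summaries from per-participant scores in entry order."""
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    k_end = min(scores1.size, scores2.size)
    looks = []
    for k in range(k_start, k_end + 1):
        a, b = scores1[:k], scores2[:k]
        looks.append({
            "k": k,
            "mean1": float(a.mean()), "sd1": float(a.std(ddof=1)),
            "mean2": float(b.mean()), "sd2": float(b.std(ddof=1)),
        })
    return looks
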
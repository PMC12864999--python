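"""Cluster-based permutation testing over channel x frequency x time data.

Voxelwise statistics (independent t, paired t, or one-way F) are
thresholded at the sample-level alpha; suprathreshold voxels are grouped
into connected clusters (adjacent frequency bin, adjacent time bin, or
neighbouring channel at the same bin), the member statistics are summed,
and each observed cluster sum is referred to the Monte-Carlo distribution
of the maximum cluster sum under random relabelling of subjects (sign
flips of within-pair differences for the paired variant).  Positive and
negative clusters are scored against their own null distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats


@dataclass
class NeighbourGraph:
    """Symmetric, irreflexive channel adjacency."""

    ch_names: list
    adjacency: np.ndarray  # boolean (n_ch, n_ch)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (len(self.ch_names),) * 2:
            raise ValueError("adjacency must be square over ch_names")
        if not (adj == adj.T).all():
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        self.adjacency = adj

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def pairs(self) -> np.ndarray:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])

    def to_json(self) -> str:
        return json.dumps({
            "ch_names": list(self.ch_names),
            "neighbours": {
                ch: [self.ch_names[j] for j in np.flatnonzero(row)]
                for ch, row in zip(self.ch_names, self.adjacency)
            },
        })

    @classmethod
    def from_template(
        cls, ch_names: Sequence[str], distance: float = 0.055
    ) -> "NeighbourGraph":
        """Adjacency from a standard 10-05 montage: channels within
        ``distance`` metres (template head) are neighbours.  The radius is
        widened until every channel has at least one neighbour."""
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            montage = mne.channels.make_standard_montage("standard_1005")
        pos = montage.get_positions()["ch_pos"]
        missing = [ch for ch in ch_names if ch not in pos]
        if missing:
            raise KeyError(f"channels missing from template montage: {missing}")
        xyz = np.array([pos[ch] for ch in ch_names])
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        radius = distance
        adj = d <= radius
        while adj.sum(axis=1).min() == 0:
            radius *= 1.2
            adj = d <= radius
        return cls(ch_names=list(ch_names), adjacency=adj)

    @classmethod
    def from_template_or_grid(cls, ch_names: Sequence[str]) -> "NeighbourGraph":
        """Template adjacency when the labels resolve on the standard
        montage (and mne is importable); chain adjacency otherwise."""
        try:
            return cls.from_template(ch_names)
        except (ImportError, KeyError):
            return cls.grid(ch_names)

    @classmethod
    def grid(cls, ch_names: Sequence[str]) -> "NeighbourGraph":
        """Chain adjacency (channel i neighbours i-1 and i+1); handy for
        synthetic layouts without template positions."""
        n = len(ch_names)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        return cls(ch_names=list(ch_names), adjacency=adj)


@dataclass
class ClusterResult:
    """One signed cluster with its summed statistic and Monte-Carlo p."""

    members: np.ndarray  # (n_members, 3) int indices (ch, freq, time)
    polarity: str        # "positive" | "negative"
    cluster_stat: float
    p_value: float = np.nan
    significant: bool = False

    def member_set(self) -> set:
        return {tuple(m) for m in self.members}


def samplewise_stat(
    groups: Sequence[np.ndarray], kind: str = "independent_t"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel statistic and p-value volumes.

    ``groups`` is a sequence of (n_subjects, ...) arrays sharing trailing
    axes.  t variants take exactly two groups (two-tailed p); the F variant
    accepts two or more (upper-tail p).
    """
    if kind in ("independent_t", "paired_t"):
        if len(groups) != 2:
            raise ValueError(f"{kind} requires exactly two groups")
        a, b = (np.asarray(g, dtype=float) for g in groups)
        if a.shape[1:] != b.shape[1:]:
            raise ValueError("groups must share voxel axes")
        if kind == "paired_t":
            if a.shape[0] != b.shape[0]:
                raise ValueError("paired test requires equal subject counts")
            d = a - b
            n = d.shape[0]
            if n < 2:
                raise ValueError("need >= 2 subjects")
            sd = d.std(axis=0, ddof=1)
            sd[sd == 0] = np.finfo(float).tiny
            t = d.mean(axis=0) / (sd / np.sqrt(n))
            df = n - 1
        else:
            n1, n2 = a.shape[0], b.shape[0]
            if min(n1, n2) < 2:
                raise ValueError("need >= 2 subjects per group")
            v1 = a.var(axis=0, ddof=1)
            v2 = b.var(axis=0, ddof=1)
            df = n1 + n2 - 2
            sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            denom = np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
            denom[denom == 0] = np.finfo(float).tiny
            t = (a.mean(axis=0) - b.mean(axis=0)) / denom
        p = 2.0 * stats.t.sf(np.abs(t), df)
        return t, p
    if kind == "F":
        gs = [np.asarray(g, dtype=float) for g in groups]
        if len(gs) < 2:
            raise ValueError("F requires >= 2 groups")
        ns = np.array([g.shape[0] for g in gs])
        if (ns < 2).any():
            raise ValueError("need >= 2 subjects per group")
        grand = np.concatenate(gs, axis=0).mean(axis=0)
        between = sum(
            n * (g.mean(axis=0) - grand) ** 2 for g, n in zip(gs, ns)
        )
        within = sum(g.var(axis=0, ddof=0) * n for g, n in zip(gs, ns))
        df1 = len(gs) - 1
        df2 = int(ns.sum()) - len(gs)
        within[within == 0] = np.finfo(float).tiny
        f = (between / df1) / (within / df2)
        p = stats.f.sf(f, df1, df2)
        return f, p
    raise ValueError(f"unknown statistic kind {kind!r}")


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


_FT_STRUCTURE = np.array(
    [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool
)  # adjacency in (freq, time): no diagonals


def _connected_sums(
    stat: np.ndarray, mask: np.ndarray, pairs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster sums and voxel labels for one polarity.

    Labels the (freq, time) plane of each channel independently, then
    merges labels of neighbouring channels wherever both are suprathreshold
    at the same (freq, time) bin.  Returns (sums, labels) where ``labels``
    maps every voxel to a cluster id (0 = background) and ``sums[k-1]`` is
    the summed statistic of cluster k.
    """
    n_ch = stat.shape[0]
    labels = np.zeros(stat.shape, dtype=np.int32)
    offset = 0
    for c in range(n_ch):
        lab, n = ndimage.label(mask[c], structure=_FT_STRUCTURE)
        if n:
            lab = lab.astype(np.int32)
            lab[lab > 0] += offset
            labels[c] = lab
            offset += n
    if offset == 0:
        return np.empty(0), labels
    uf = _UnionFind(offset + 1)
    for c1, c2 in pairs:
        common = mask[c1] & mask[c2]
        if common.any():
            l1 = labels[c1][common]
            l2 = labels[c2][common]
            for a, b in set(zip(l1.tolist(), l2.tolist())):
                uf.union(a, b)
    roots = np.array([uf.find(i) for i in range(offset + 1)])
    # compress root ids to 1..K
    uniq, compact = np.unique(roots[1:], return_inverse=True)
    remap = np.zeros(offset + 1, dtype=np.int32)
    remap[1:] = compact + 1
    labels = remap[labels]
    k = len(uniq)
    sums = np.zeros(k)
    np.add.at(sums, labels[mask] - 1, stat[mask])
    return sums, labels


def form_clusters(
    stat: np.ndarray,
    p: np.ndarray,
    alpha_sample: float = 0.05,
    neighbours: Optional[NeighbourGraph] = None,
    signed: bool = True,
) -> list[ClusterResult]:
    """Partition suprathreshold voxels into connected clusters.

    Voxels with p exactly equal to ``alpha_sample`` are excluded (strict
    inequality).  For signed statistics, positive and negative voxels form
    separate clusters.
    """
    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    if stat.shape != p.shape:
        raise ValueError("stat and p volumes must share axes")
    if stat.ndim == 2:  # (ch, time) or (ch, freq): treat as 1-bin 3rd axis
        stat = stat[:, :, None]
        p = p[:, :, None]
    pairs = neighbours.pairs() if neighbours is not None else np.empty((0, 2),
                                                                       int)
    sig = p < alpha_sample
    results: list[ClusterResult] = []
    polarities = [("positive", sig & (stat > 0)), ("negative", sig & (stat < 0))] \
        if signed else [("positive", sig)]
    for name, mask in polarities:
        sums, labels = _connected_sums(stat, mask, pairs)
        for k, s in enumerate(sums, start=1):
            members = np.argwhere(labels == k)
            results.append(ClusterResult(
                members=members, polarity=name, cluster_stat=float(s),
            ))
    results.sort(key=lambda c: -abs(c.cluster_stat))
    return results


def _max_cluster_sums(
    stat: np.ndarray, p: np.ndarray, alpha_sample: float,
    pairs: np.ndarray, signed: bool,
) -> tuple[float, float]:
    """(max positive cluster sum, min negative cluster sum) of one volume."""
    sig = p < alpha_sample
    pos_sums, _ = _connected_sums(stat, sig & (stat > 0), pairs)
    max_pos = pos_sums.max() if pos_sums.size else 0.0
    if not signed:
        return max_pos, 0.0
    neg_sums, _ = _connected_sums(stat, sig & (stat < 0), pairs)
    min_neg = neg_sums.min() if neg_sums.size else 0.0
    return max_pos, min_neg


def _stat_volume(gs: Sequence[np.ndarray], kind: str) -> np.ndarray:
    """Statistic volume only (no p) — hot path of the permutation loop."""
    if kind == "paired_t":
        d = gs[0] - gs[1]
        n = d.shape[0]
        sd = d.std(axis=0, ddof=1)
        sd[sd == 0] = np.finfo(float).tiny
        return d.mean(axis=0) / (sd / np.sqrt(n))
    if kind == "independent_t":
        a, b = gs
        n1, n2 = a.shape[0], b.shape[0]
        df = n1 + n2 - 2
        sp = ((n1 - 1) * a.var(axis=0, ddof=1)
              + (n2 - 1) * b.var(axis=0, ddof=1)) / df
        denom = np.sqrt(sp * (1.0 / n1 + 1.0 / n2))
        denom[denom == 0] = np.finfo(float).tiny
        return (a.mean(axis=0) - b.mean(axis=0)) / denom
    # F
    ns = np.array([g.shape[0] for g in gs])
    grand = np.concatenate(gs, axis=0).mean(axis=0)
    between = sum(n * (g.mean(axis=0) - grand) ** 2 for g, n in zip(gs, ns))
    within = sum(g.var(axis=0, ddof=0) * n for g, n in zip(gs, ns))
    within[within == 0] = np.finfo(float).tiny
    df1 = len(gs) - 1
    df2 = int(ns.sum()) - len(gs)
    return (between / df1) / (within / df2)


def _critical_value(gs: Sequence[np.ndarray], kind: str,
                    alpha_sample: float) -> float:
    ns = [g.shape[0] for g in gs]
    if kind == "paired_t":
        return float(stats.t.ppf(1 - alpha_sample / 2, ns[0] - 1))
    if kind == "independent_t":
        return float(stats.t.ppf(1 - alpha_sample / 2, sum(ns) - 2))
    return float(stats.f.ppf(1 - alpha_sample, len(gs) - 1,
                             sum(ns) - len(gs)))


def _max_sums_fast(
    stat: np.ndarray, crit: float, pairs: np.ndarray, signed: bool
) -> tuple[float, float]:
    """As :func:`_max_cluster_sums` but thresholding |stat| > crit directly
    (equivalent to p < alpha for the matching two-tailed/upper-tail test)."""
    pos_sums, _ = _connected_sums(stat, stat > crit, pairs)
    max_pos = pos_sums.max() if pos_sums.size else 0.0
    if not signed:
        return max_pos, 0.0
    neg_sums, _ = _connected_sums(stat, stat < -crit, pairs)
    min_neg = neg_sums.min() if neg_sums.size else 0.0
    return max_pos, min_neg


def permutation_test(
    groups: Sequence[np.ndarray],
    kind: str = "independent_t",
    n_randomizations: int = 4000,
    alpha_sample: float = 0.05,
    alpha_cluster: float = 0.025,
    neighbours: Optional[NeighbourGraph] = None,
    rng: Optional[np.random.Generator] = None,
    warn_threshold: int = 100,
) -> dict:
    """Score observed clusters against the Monte-Carlo max-cluster null.

    Returns a dict with keys ``clusters`` (scored :class:`ClusterResult`
    list), ``null_max_positive`` / ``null_max_negative`` (the null
    distributions), and ``provenance``.  Cluster p-values use the
    (b + 1) / (R + 1) convention so the observed labelling counts itself.
    """
    if rng is None:
        rng = np.random.default_rng()
    provenance = {
        "kind": kind, "n_randomizations": int(n_randomizations),
        "alpha_sample": alpha_sample, "alpha_cluster": alpha_cluster,
    }
    if n_randomizations < warn_threshold:
        provenance["warning"] = (
            f"only {n_randomizations} randomizations; Monte-Carlo p-values "
            "are coarse"
        )
    gs = [np.asarray(g, dtype=float) for g in groups]
    signed = kind != "F"
    stat, p = samplewise_stat(gs, kind)
    work_stat = stat[:, :, None] if stat.ndim == 2 else stat
    work_p = p[:, :, None] if p.ndim == 2 else p
    pairs = neighbours.pairs() if neighbours is not None else np.empty((0, 2),
                                                                       int)
    observed = form_clusters(stat, p, alpha_sample, neighbours, signed=signed)

    null_pos = np.empty(n_randomizations)
    null_neg = np.empty(n_randomizations)
    crit = _critical_value(gs, kind, alpha_sample)
    if kind == "paired_t":
        diffs = (gs[0] - gs[1]).astype(float)
        n = diffs.shape[0]
        zero = np.zeros_like(diffs)
        for r in range(n_randomizations):
            flips = rng.choice([-1.0, 1.0], size=n)
            flipped = diffs * flips.reshape((-1,) + (1,) * (diffs.ndim - 1))
            s = _stat_volume([flipped, zero], "paired_t")
            s = s[:, :, None] if s.ndim == 2 else s
            null_pos[r], null_neg[r] = _max_sums_fast(s, crit, pairs, signed)
    else:
        pooled = np.concatenate(gs, axis=0)
        sizes = [g.shape[0] for g in gs]
        edges = np.cumsum([0] + sizes)
        for r in range(n_randomizations):
            perm = rng.permutation(pooled.shape[0])
            shuffled = [
                pooled[perm[edges[i]:edges[i + 1]]] for i in range(len(gs))
            ]
            s = _stat_volume(shuffled, kind)
            s = s[:, :, None] if s.ndim == 2 else s
            null_pos[r], null_neg[r] = _max_sums_fast(s, crit, pairs, signed)

    for cl in observed:
        if cl.polarity == "positive":
            b = int((null_pos >= cl.cluster_stat).sum())
        else:
            b = int((null_neg <= cl.cluster_stat).sum())
        cl.p_value = (b + 1.0) / (n_randomizations + 1.0)
        cl.significant = bool(cl.p_value < alpha_cluster)
    if neighbours is not None:
        provenance["neighbour_graph"] = json.loads(neighbours.to_json())
    return {
        "clusters": observed,
        "null_max_positive": null_pos,
        "null_max_negative": null_neg,
        "stat": stat,
        "p": p,
        "provenance": provenance,
    }


def cluster_summary(result: dict) -> list[dict]:
    """JSON-serialisable summary of a permutation test result."""
    return [
        {
            "polarity": c.polarity,
            "cluster_stat": c.cluster_stat,
            "p_value": c.p_value,
            "significant": c.significant,
            "n_members": int(len(c.members)),
        }
        for c in result["clusters"]
    ]
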
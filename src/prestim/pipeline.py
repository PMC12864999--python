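"""End-to-end study replica: simulate -> preprocess -> TFR -> screening ->
cluster statistics -> behavioural inference, under one seeded config.

The stages mirror the study's participant flow: entrainment screening
(10% / 500 ms criterion) excludes first, then the false-alarm-rate rule;
survivors enter the EEG group contrasts (cluster-based permutation on the
late-window percent-change volumes) and the behavioural Bayes-factor
contrasts with their sequential traces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import study_constants as sc
from .bayes import (jzs_bf_two_sample, looks_from_scores, sequential_monitor)
from .clusterperm import NeighbourGraph, cluster_summary, permutation_test
from .containers import EpochSet
from .entrainment import assess_entrainment
from .preprocessing import preprocess_recording
from .sdt import ne_subsample_match, score_cohort
from .simulate import (GROUP_FREQUENCIES, CohortConfig, simulate_behavior,
                       simulate_participant_eeg)
from .timefreq import baseline_percent_change, tfr_hanning


@dataclass
class StudyConfig:
    """All pipeline parameters; defaults are the study's printed values."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    jump_threshold: float = 60.0
    muscle_threshold: float = 30.0
    bandpass_low: float = 0.5
    bandpass_high: float = 40.0
    tfr_window_s: float = 0.5
    tfr_step_s: float = 0.1
    entrain_threshold_pct: float = 10.0
    entrain_min_duration_ms: float = 500.0
    n_randomizations: int = 4000
    alpha_sample: float = 0.05
    alpha_cluster: float = 0.025
    k_start: int = sc.SEQUENTIAL_K_START
    k_max: int = sc.SEQUENTIAL_K_MAX
    bf_thresholds: tuple = sc.BF_THRESHOLDS
    eeg_trials_per_participant: Optional[int] = None  # None = full 141
    out_dir: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        cfg = cls(cohort=cohort, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


#: Behavioural contrasts: (name, group1, group2, sidedness)
BEHAVIORAL_CONTRASTS = [
    ("theta_vs_control", "theta", "control", "one_sided_greater"),
    ("alpha_vs_control", "alpha", "control", "one_sided_greater"),
    ("theta_vs_alpha", "theta", "alpha", "two_sided"),
]
NE_CONTRASTS = [
    ("theta_vs_ne", "theta", "ne", "one_sided_greater"),
    ("alpha_vs_ne", "alpha", "ne", "one_sided_greater"),
]


def process_participant(
    config: StudyConfig, group: str, rng: np.random.Generator,
):
    """Simulate and fully preprocess one participant's EEG; return the
    percent-change TFR volume and the entrainment assessment (None for
    groups without a stimulation frequency)."""
    rec, _log = simulate_participant_eeg(
        config.cohort, group, rng,
        n_trials=config.eeg_trials_per_participant,
    )
    epochs = preprocess_recording(
        rec, low=config.bandpass_low, high=config.bandpass_high,
        jump_threshold=config.jump_threshold,
        muscle_threshold=config.muscle_threshold,
    ).kept()
    tfr = tfr_hanning(epochs, window_len=config.tfr_window_s,
                      step=config.tfr_step_s)
    pc = baseline_percent_change(tfr)
    assessment = None
    if group in GROUP_FREQUENCIES:
        assessment = assess_entrainment(
            pc, GROUP_FREQUENCIES[group],
            threshold=config.entrain_threshold_pct,
            min_duration_ms=config.entrain_min_duration_ms,
        )
    return pc, assessment


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline and return the study report.

    The report contains the entrainment assessments and exclusions,
    cluster results for the EEG contrasts, the SDT table, the BF table
    with sequential traces, and provenance.  Every stochastic stage is
    driven by ``config.seed``.
    """
    root_ss = np.random.SeedSequence(config.seed)
    eeg_ss, beh_ss, stat_ss = root_ss.spawn(3)
    cohort = config.cohort
    report: dict = {"provenance": {"seed": config.seed,
                                   "config": config.to_dict()}}
    stage = "simulate_eeg"
    try:
        # --- EEG stages -------------------------------------------------
        volumes: dict[str, list] = {}
        assessments = []
        entrain_excluded: dict[str, set] = {}
        eeg_groups = [g for g in cohort.groups if g != "ne"]
        child_ss = eeg_ss.spawn(len(eeg_groups) * cohort.k_per_group)
        si = 0
        stage = "preprocess/tfr/screening"
        for group in eeg_groups:
            volumes[group] = []
            entrain_excluded[group] = set()
            for p in range(cohort.k_per_group):
                pid = f"{group}_{p:03d}"
                rng = np.random.default_rng(child_ss[si]); si += 1
                pc, assessment = process_participant(config, group, rng)
                volumes[group].append(pc.power)
                if assessment is not None:
                    assessment.participant_id = pid
                    assessments.append(assessment)
                    if not assessment.passed:
                        entrain_excluded[group].add(p)

        # --- cluster statistics on the late window ---------------------
        stage = "cluster_test"
        graph = NeighbourGraph.from_template_or_grid(cohort.scalp_channels)
        cluster_results = {}
        for name, g1, g2 in [("theta_vs_control", "theta", "control"),
                             ("alpha_vs_control", "alpha", "control")]:
            if g1 not in volumes or g2 not in volumes:
                continue
            arr1 = _stack_late(volumes[g1], entrain_excluded.get(g1, set()),
                               cohort, config)
            arr2 = _stack_late(volumes[g2], entrain_excluded.get(g2, set()),
                               cohort, config)
            if arr1.shape[0] < 2 or arr2.shape[0] < 2:
                cluster_results[name] = {"skipped": "too few participants"}
                continue
            res = permutation_test(
                [arr1, arr2], kind="independent_t",
                n_randomizations=config.n_randomizations,
                alpha_sample=config.alpha_sample,
                alpha_cluster=config.alpha_cluster,
                neighbours=graph,
                rng=np.random.default_rng(stat_ss.spawn(1)[0]),
            )
            # keep the largest clusters only; the tail is sub-threshold noise
            cluster_results[name] = cluster_summary(res)[:25]

        # --- behaviour --------------------------------------------------
        stage = "behavior"
        frames = []
        beh_children = beh_ss.spawn(len(cohort.groups))
        for gi, group in enumerate(cohort.groups):
            rng = np.random.default_rng(beh_children[gi])
            k = cohort.k_per_group if group != "ne" else cohort.ne_pool_k
            for p in range(k):
                table, truth = simulate_behavior(cohort, group, rng)
                table.insert(0, "participant", f"{group}_{p:03d}")
                table.insert(1, "group", group)
                table["true_dprime"] = truth["true_dprime"]
                frames.append(table)
        behavior = pd.concat(frames, ignore_index=True)
        sdt_table = score_cohort(behavior)

        # --- exclusions bookkeeping -------------------------------------
        stage = "exclusions"
        excl_rows = []
        for _, row in sdt_table.iterrows():
            pid, group = row["participant"], row["group"]
            p_idx = int(pid.split("_")[-1])
            ent = p_idx in entrain_excluded.get(group, set())
            fa = bool(row["excluded"])
            reason = ("both" if ent and fa else
                      "entrainment" if ent else
                      "fa_rate" if fa else None)
            excl_rows.append({"participant": pid, "group": group,
                              "excluded": reason is not None,
                              "reason": reason})
        exclusions = pd.DataFrame(excl_rows)
        keep_ids = set(exclusions.loc[~exclusions["excluded"], "participant"])
        analyzed = sdt_table[sdt_table["participant"].isin(keep_ids)]

        # --- Bayes factors and sequential traces ------------------------
        stage = "bayes"
        scores = {
            g: analyzed.loc[analyzed["group"] == g, "dprime"].to_numpy()
            for g in cohort.groups
        }
        if "ne" in scores and scores["ne"].size:
            target = min(cohort.k_per_group, scores["ne"].size)
            match = ne_subsample_match(
                scores["ne"], target_k=target, draws=50,
                rng=np.random.default_rng(stat_ss.spawn(1)[0]),
            )
            scores["ne"] = scores["ne"][match.indices]
            report["ne_subsample"] = {
                "indices": match.indices.tolist(),
                "mean_difference": match.mean_difference,
                "candidate_means": match.candidate_means.tolist(),
            }
        bf_rows = []
        traces = {}
        contrasts = list(BEHAVIORAL_CONTRASTS)
        if "ne" in cohort.groups:
            contrasts += NE_CONTRASTS
        for name, g1, g2, sided in contrasts:
            s1, s2 = scores.get(g1), scores.get(g2)
            if s1 is None or s2 is None or min(s1.size, s2.size) < 2:
                continue
            bf = jzs_bf_two_sample(
                s1.mean(), s1.std(ddof=1), s1.size,
                s2.mean(), s2.std(ddof=1), s2.size,
                sidedness=sided,
            )
            bf_rows.append({
                "contrast": name, "bf10": bf.bf10, "t": bf.t_stat,
                "n1": bf.n1, "n2": bf.n2, "sidedness": sided,
            })
            k_start = min(config.k_start, min(s1.size, s2.size))
            looks = looks_from_scores(s1, s2, k_start=k_start)
            if looks:
                traces[name] = sequential_monitor(
                    looks, contrast=name, thresholds=config.bf_thresholds,
                    k_start=k_start, k_max=config.k_max, sidedness=sided,
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    n_total = len(exclusions)
    report.update({
        "entrainment_assessments": [
            {"participant": a.participant_id, "passed": a.passed,
             "max_percent_change": a.max_percent_change,
             "sustained_ms": a.sustained_ms}
            for a in assessments
        ],
        "exclusions": exclusions,
        "exclusion_counts": {
            "simulated": n_total,
            "entrainment": int((exclusions["reason"] == "entrainment").sum()),
            "fa_rate": int((exclusions["reason"] == "fa_rate").sum()),
            "both": int((exclusions["reason"] == "both").sum()),
            "analyzed": int((~exclusions["excluded"]).sum()),
        },
        "cluster_results": cluster_results,
        "sdt_table": sdt_table,
        "bf_table": pd.DataFrame(bf_rows),
        "sequential_traces": traces,
    })
    if config.out_dir:
        _write_report(report, config)
    return report


def _stack_late(vols, excluded_idx, cohort, config) -> np.ndarray:
    """Stack per-subject percent-change volumes, late window only."""
    from .timefreq import DEFAULT_TFR_TIMES
    times = DEFAULT_TFR_TIMES
    late = (times >= -1.1 - 1e-9) & (times <= -0.1 + 1e-9)
    scalp_idx = [i for i, c in enumerate(cohort.channel_labels)
                 if c in cohort.scalp_channels]
    kept = [v[np.ix_(scalp_idx, np.arange(v.shape[1]), np.flatnonzero(late))]
            for i, v in enumerate(vols) if i not in excluded_idx]
    return np.stack(kept) if kept else np.empty((0,))


def _write_report(report: dict, config: StudyConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["exclusions"].to_csv(out / "exclusions.tsv", sep="\t", index=False)
    report["sdt_table"].to_csv(out / "sdt_table.tsv", sep="\t", index=False)
    report["bf_table"].to_csv(out / "bf_table.tsv", sep="\t", index=False)
    for name, tr in report["sequential_traces"].items():
        pd.DataFrame({"k": tr.k_trace, "bf10": tr.bf_trace}).to_csv(
            out / f"sequential_{name}.tsv", sep="\t", index=False
        )
    serializable = {
        "provenance": report["provenance"],
        "exclusion_counts": report["exclusion_counts"],
        "cluster_results": report["cluster_results"],
        "entrainment_assessments": report["entrainment_assessments"],
        "sequential_decisions": {
            name: {"decision": tr.decision, "decided_at_k": tr.decided_at_k}
            for name, tr in report["sequential_traces"].items()
        },
    }
    with open(out / "report.json", "w") as f:
        json.dump(serializable, f, indent=2, default=str)
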
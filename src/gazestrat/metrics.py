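"""The 14 participant-level gaze metrics of the matrix-reasoning strategy set.

Aggregation conventions (the "totals convention"):

* transition counts (matrix-matrix, matrix-answer, answer-answer) and
  fixation counts are TOTALS over the scored trials;
* time-type metrics (item time, latency, fixation durations) are MEANS per
  trial or per fixation;
* visit metrics are means per cell/choice per trial;
* the matrix/answer time ratio is total matrix dwell over total answer dwell.

These make the matrix-answer transition *rate* identity exact:
``rate = n_ma_transitions / (avg_item_time_s * n_scored_trials)``.

Transition metrics are computed on the collapsed sequence (consecutive
fixations in the same AOI merged into one element), the same representation
the scanpath clustering uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ItemKey
from .preprocess import TrialScanpath, is_answer, is_matrix

#: stable output column order, one column per metric
METRIC_COLUMNS = (
    "avg_item_time_s",
    "n_mm_transitions",
    "n_ma_transitions",
    "n_aa_transitions",
    "latency_first_answer_ms",
    "matrix_answer_time_ratio",
    "visits_per_matrix_cell",
    "visits_per_wrong_answer",
    "n_fix_matrix",
    "mean_fixdur_matrix_ms",
    "n_fix_answers",
    "mean_fixdur_answers_ms",
    "pct_cluster2",
    "ma_transition_rate_per_s",
)


def collapse(sequence: list[str]) -> list[str]:
    """Merge maximal runs of identical consecutive elements into one.

    Idempotent; never longer than its input; empty in, empty out.
    """
    out: list[str] = []
    for item in sequence:
        if not out or out[-1] != item:
            out.append(item)
    return out


def collapse_aoi_sequence(scanpath: TrialScanpath) -> list[str]:
    """Collapsed AOI sequence of one filtered trial (cell/choice granularity)."""
    return collapse(scanpath.sequence)


def count_transitions(seq: list[str]) -> tuple[int, int, int]:
    """(matrix-matrix, matrix-answer, answer-answer) transition counts.

    ``seq`` must be a collapsed sequence; matrix-answer counts both
    directions. The three counts always sum to ``len(seq) - 1`` (0 for
    sequences of length <= 1).
    """
    mm = ma = aa = 0
    for a, b in zip(seq, seq[1:]):
        if is_matrix(a) and is_matrix(b):
            mm += 1
        elif is_answer(a) and is_answer(b):
            aa += 1
        else:
            ma += 1
    return mm, ma, aa


@dataclass
class GazeMetrics:
    """One participant's metric vector with missingness reasons."""

    participant_id: str
    values: dict[str, float]  # keyed by METRIC_COLUMNS; NaN where missing
    missing: dict[str, str]  # metric -> reason
    n_scored_trials: int

    def as_row(self) -> dict[str, float | str | int]:
        row: dict[str, float | str | int] = {"participant_id": self.participant_id}
        row.update({c: self.values.get(c, np.nan) for c in METRIC_COLUMNS})
        row["n_scored_trials"] = self.n_scored_trials
        row["missing"] = ";".join(sorted(self.missing)) if self.missing else ""
        return row


def compute_participant_metrics(
    trials: list[TrialScanpath],
    keys: list[ItemKey],
    cluster_labels: dict[str, int] | None = None,
) -> GazeMetrics:
    """Compute the 14 metrics for one participant from filtered scanpaths.

    ``cluster_labels`` maps trial_id -> {1, 2}; without it the cluster-share
    metric is reported missing. Trials left empty by filtering are excluded
    from every aggregate (and from the trial count in denominators).
    """
    if not trials:
        raise ValueError("no trials supplied")
    pid = trials[0].participant_id
    correct = {k.trial_id: k.correct_choice for k in keys}
    scored = [t for t in trials if not t.empty]
    if not scored:
        raise ValueError(f"participant {pid!r} has no non-empty scored trials")
    n = len(scored)

    values: dict[str, float] = {}
    missing: dict[str, str] = {}

    values["avg_item_time_s"] = float(np.mean([t.trial_duration_ms for t in scored])) / 1000.0

    mm = ma = aa = 0
    total_matrix_visits = 0
    total_wrong_visits = 0
    for t in scored:
        seq = collapse_aoi_sequence(t)
        a, b, c = count_transitions(seq)
        mm, ma, aa = mm + a, ma + b, aa + c
        corr_label = f"A{correct[t.trial_id]}" if t.trial_id in correct else None
        for el in seq:  # one collapsed element == one visit (entry event)
            if is_matrix(el):
                total_matrix_visits += 1
            elif is_answer(el) and el != corr_label:
                total_wrong_visits += 1
    values["n_mm_transitions"] = float(mm)
    values["n_ma_transitions"] = float(ma)
    values["n_aa_transitions"] = float(aa)
    values["visits_per_matrix_cell"] = total_matrix_visits / (9.0 * n)
    values["visits_per_wrong_answer"] = total_wrong_visits / (7.0 * n)

    latencies = []
    for t in scored:
        ans = t.fixations[t.fixations["aoi"].map(is_answer)]
        if len(ans):
            latencies.append(float(ans["onset_ms"].iloc[0]))
    if latencies:
        values["latency_first_answer_ms"] = float(np.mean(latencies))
    else:
        values["latency_first_answer_ms"] = np.nan
        missing["latency_first_answer_ms"] = "no answer fixation in any trial"

    matrix_dwell = sum(v for t in scored for k, v in t.dwell_ms.items() if is_matrix(k))
    answer_dwell = sum(v for t in scored for k, v in t.dwell_ms.items() if is_answer(k))
    if answer_dwell > 0:
        values["matrix_answer_time_ratio"] = matrix_dwell / answer_dwell
    else:
        values["matrix_answer_time_ratio"] = np.nan
        missing["matrix_answer_time_ratio"] = "zero answer dwell"

    mfix = pd.concat([t.fixations[t.fixations["aoi"].map(is_matrix)] for t in scored])
    afix = pd.concat([t.fixations[t.fixations["aoi"].map(is_answer)] for t in scored])
    values["n_fix_matrix"] = float(len(mfix))
    values["n_fix_answers"] = float(len(afix))
    if len(mfix):
        values["mean_fixdur_matrix_ms"] = float(mfix["duration_ms"].mean())
    else:
        values["mean_fixdur_matrix_ms"] = np.nan
        missing["mean_fixdur_matrix_ms"] = "no matrix fixations"
    if len(afix):
        values["mean_fixdur_answers_ms"] = float(afix["duration_ms"].mean())
    else:
        values["mean_fixdur_answers_ms"] = np.nan
        missing["mean_fixdur_answers_ms"] = "no answer fixations"

    if cluster_labels is not None:
        labels = [cluster_labels[t.trial_id] for t in scored if t.trial_id in cluster_labels]
        if labels:
            values["pct_cluster2"] = 100.0 * sum(l == 2 for l in labels) / len(labels)
        else:
            values["pct_cluster2"] = np.nan
            missing["pct_cluster2"] = "no labeled trials"
    else:
        values["pct_cluster2"] = np.nan
        missing["pct_cluster2"] = "cluster labels not supplied"

    item_time = values["avg_item_time_s"]
    if item_time > 0:
        values["ma_transition_rate_per_s"] = ma / (item_time * n)
    else:
        values["ma_transition_rate_per_s"] = np.nan
        missing["ma_transition_rate_per_s"] = "zero total item time"

    return GazeMetrics(participant_id=pid, values=values, missing=missing, n_scored_trials=n)


def participant_metrics_table(
    scanpaths: list[TrialScanpath],
    keys: list[ItemKey],
    cluster_labels: dict[tuple[str, str], int] | None = None,
    participants: list[str] | None = None,
) -> pd.DataFrame:
    """Metric table, one row per participant.

    ``cluster_labels`` maps (participant_id, trial_id) -> {1, 2}.
    """
    by_pid: dict[str, list[TrialScanpath]] = {}
    for sp in scanpaths:
        by_pid.setdefault(sp.participant_id, []).append(sp)
    pids = participants if participants is not None else sorted(by_pid)
    rows = []
    for pid in pids:
        per_trial = (
            {tid: lab for (p, tid), lab in cluster_labels.items() if p == pid}
            if cluster_labels is not None
            else None
        )
        rows.append(compute_participant_metrics(by_pid[pid], keys, per_trial).as_row())
    return pd.DataFrame(rows)
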
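"""Fixation tagging, trial-level filtering and participant quality control.

Filtering follows the study protocol for cognitive fixations: the first raw
fixation of every trial is dropped unconditionally, fixations outside the
matrix and answer AOIs are discarded, and only fixations at or above the
minimum duration (default 100 ms, the recorder's own floor) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AoiLayout, ItemKey

MATRIX_LABELS = tuple(f"M{r}{c}" for r in range(3) for c in range(3))
ANSWER_LABELS = tuple(f"A{k}" for k in range(8))


def is_matrix(tag: str) -> bool:
    return tag.startswith("M")


def is_answer(tag: str) -> bool:
    return tag.startswith("A")


def tag_fixations(fixations: pd.DataFrame, layout: AoiLayout) -> pd.DataFrame:
    """Append an ``aoi`` column ('M{r}{c}', 'A{k}' or 'OUT') to a fixation table.

    The tag depends only on (x, y) and the layout's half-open rectangles, so
    every fixation receives exactly one tag.
    """
    out = fixations.copy()
    out["aoi"] = [layout.tag(x, y) for x, y in zip(out["x_px"], out["y_px"])]
    return out


@dataclass
class TrialScanpath:
    """One trial's retained, tagged fixations in time order."""

    participant_id: str
    trial_id: str
    trial_index: int
    fixations: pd.DataFrame  # canonical columns + 'aoi'; no 'OUT' tags
    dwell_ms: dict[str, float]
    trial_duration_ms: float

    @property
    def empty(self) -> bool:
        return len(self.fixations) == 0

    @property
    def sequence(self) -> list[str]:
        """AOI labels of retained fixations, fixation-by-fixation."""
        return list(self.fixations["aoi"])


def filter_trial(
    trial: pd.DataFrame,
    min_duration_ms: float = 100.0,
    drop_first: bool = True,
    drop_outside: bool = True,
    strict_threshold: bool = False,
) -> TrialScanpath:
    """Apply the fixation filters to one tagged trial.

    Order of application: (1) drop the first raw fixation regardless of its
    tag or duration, (2) drop OUT-tagged fixations, (3) keep fixations with
    duration >= ``min_duration_ms`` (strictly > when ``strict_threshold``).
    An empty result is a valid (flagged) scanpath, not an error.
    """
    if "aoi" not in trial.columns:
        raise ValueError("trial is not tagged; run tag_fixations first")
    t = trial.sort_values("onset_ms", kind="stable").reset_index(drop=True)
    pid = str(t["participant_id"].iloc[0])
    tid = str(t["trial_id"].iloc[0])
    tidx = int(t["trial_index"].iloc[0])
    if drop_first:
        t = t.iloc[1:]
    if drop_outside:
        t = t[t["aoi"] != "OUT"]
    if strict_threshold:
        t = t[t["duration_ms"] > min_duration_ms]
    else:
        t = t[t["duration_ms"] >= min_duration_ms]
    t = t.reset_index(drop=True)
    dwell = t.groupby("aoi")["duration_ms"].sum().to_dict()
    duration = float(t["onset_ms"].iloc[-1] + t["duration_ms"].iloc[-1]) if len(t) else 0.0
    return TrialScanpath(
        participant_id=pid,
        trial_id=tid,
        trial_index=tidx,
        fixations=t,
        dwell_ms={k: float(v) for k, v in dwell.items()},
        trial_duration_ms=duration,
    )


def filter_fixations(
    tagged: pd.DataFrame,
    keys: list[ItemKey] | None = None,
    *,
    include_practice: bool = False,
    **filter_kwargs,
) -> list[TrialScanpath]:
    """Filter every (participant, trial) group; practice items are dropped.

    Trials are returned in (participant_id, trial_index) order. When ``keys``
    is given, trials absent from the key list are ignored.
    """
    practice = {k.trial_id for k in keys if k.is_practice} if keys else set()
    known = {k.trial_id for k in keys} if keys else None

    min_duration_ms = filter_kwargs.pop("min_duration_ms", 100.0)
    drop_first = filter_kwargs.pop("drop_first", True)
    drop_outside = filter_kwargs.pop("drop_outside", True)
    strict = filter_kwargs.pop("strict_threshold", False)
    if filter_kwargs:
        raise TypeError(f"unknown filter option(s): {sorted(filter_kwargs)}")
    if "aoi" not in tagged.columns:
        raise ValueError("fixations are not tagged; run tag_fixations first")

    t = tagged
    if known is not None:
        wanted = known if include_practice else known - practice
        t = t[t["trial_id"].isin(wanted)]
    elif not include_practice and practice:
        t = t[~t["trial_id"].isin(practice)]
    t = t.sort_values(
        ["participant_id", "trial_index", "onset_ms"], kind="stable"
    ).reset_index(drop=True)

    # vectorized application of the same rules as filter_trial
    keep = pd.Series(True, index=t.index)
    if drop_first:
        keep &= t.duplicated(["participant_id", "trial_id"])  # False only on first row
    if drop_outside:
        keep &= t["aoi"] != "OUT"
    if strict:
        keep &= t["duration_ms"] > min_duration_ms
    else:
        keep &= t["duration_ms"] >= min_duration_ms
    kept = t[keep]
    groups = {k: g for k, g in kept.groupby(["participant_id", "trial_id"], sort=False)}

    out: list[TrialScanpath] = []
    trial_ids = t[["participant_id", "trial_id", "trial_index"]].drop_duplicates()
    empty = kept.iloc[0:0]
    for pid, tid, tidx in trial_ids.itertuples(index=False):
        g = groups.get((pid, tid), empty).reset_index(drop=True)
        dwell = g.groupby("aoi")["duration_ms"].sum().to_dict() if len(g) else {}
        duration = float(g["onset_ms"].iloc[-1] + g["duration_ms"].iloc[-1]) if len(g) else 0.0
        out.append(
            TrialScanpath(
                participant_id=str(pid),
                trial_id=str(tid),
                trial_index=int(tidx),
                fixations=g,
                dwell_ms={k: float(v) for k, v in dwell.items()},
                trial_duration_ms=duration,
            )
        )
    out.sort(key=lambda s: (s.participant_id, s.trial_index))
    return out


@dataclass
class QcReport:
    """Per-participant exclusion decisions with reasons."""

    table: pd.DataFrame  # participant_id, valid_ratio, mean_fix_per_trial, excluded, reason
    retained: list[str] = field(default_factory=list)

    def reasons(self, participant_id: str) -> str:
        row = self.table.loc[self.table["participant_id"] == participant_id, "reason"]
        return str(row.iloc[0]) if len(row) else ""


def qc_participants(
    scanpaths: list[TrialScanpath],
    scores: pd.DataFrame | None = None,
    valid_ratio_min: float = 0.50,
    min_fix_per_trial: float = 3.0,
    score_sd_limit: float = 3.0,
    tracking_ratio: pd.Series | None = None,
) -> QcReport:
    """Participant-level quality control.

    A participant is excluded when any rule fires: validity ratio below
    ``valid_ratio_min`` (the fraction of trials with a non-empty filtered
    scanpath, or an externally supplied tracking ratio when available), mean
    fixations per trial below ``min_fix_per_trial`` ("two or fewer"), or any
    score more than ``score_sd_limit`` SDs from the cohort mean. The score
    rule runs on the cohort that survives the gaze rules and skips columns
    with zero spread.
    """
    rows = []
    by_pid: dict[str, list[TrialScanpath]] = {}
    for sp in scanpaths:
        by_pid.setdefault(sp.participant_id, []).append(sp)
    if not by_pid:
        raise ValueError("no scanpaths supplied to qc_participants")

    for pid in sorted(by_pid):
        trials = by_pid[pid]
        n_trials = len(trials)
        nonempty = sum(not t.empty for t in trials)
        if tracking_ratio is not None and pid in tracking_ratio.index:
            ratio = float(tracking_ratio.loc[pid])
        else:
            ratio = nonempty / n_trials if n_trials else 0.0
        mean_fix = float(np.mean([len(t.fixations) for t in trials])) if n_trials else 0.0
        reasons = []
        if ratio < valid_ratio_min:
            reasons.append("low validity ratio")
        if mean_fix < min_fix_per_trial:
            reasons.append("low fixation count")
        rows.append(
            {
                "participant_id": pid,
                "valid_ratio": ratio,
                "mean_fix_per_trial": mean_fix,
                "excluded": bool(reasons),
                "reason": "; ".join(reasons),
            }
        )
    report = pd.DataFrame(rows)

    if scores is not None and score_sd_limit is not None:
        kept = report.loc[~report["excluded"], "participant_id"]
        sc = scores[scores["participant_id"].isin(kept)]
        numeric = sc.select_dtypes("number")
        for col in numeric.columns:
            vals = numeric[col]
            mu, sd = float(vals.mean()), float(vals.std(ddof=1))
            if not np.isfinite(sd) or sd == 0.0:
                continue  # degenerate spread: nobody excluded on this column
            flagged = sc.loc[(vals - mu).abs() > score_sd_limit * sd, "participant_id"]
            for pid in flagged:
                i = report.index[report["participant_id"] == pid][0]
                report.loc[i, "excluded"] = True
                reason = report.loc[i, "reason"]
                extra = f"score outlier ({col})"
                report.loc[i, "reason"] = f"{reason}; {extra}" if reason else extra

    retained = sorted(report.loc[~report["excluded"], "participant_id"])
    if not retained:
        raise ValueError("quality control excluded every participant")
    return QcReport(table=report, retained=retained)
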
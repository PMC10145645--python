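import numpy as np
import pandas as pd
import pytest

from gazestrat.preprocess import (
    filter_fixations,
    filter_trial,
    qc_participants,
    tag_fixations,
)
from gazestrat.synth import SyntheticConfig, simulate_study

from conftest import make_trial_frame, rect_center


def test_tagging_centres_and_outside(layout):
    cx, cy = rect_center(layout.matrix_cells[(0, 0)])
    assert layout.tag(cx, cy) == "M00"
    ax, ay = rect_center(layout.answer_choices[5])
    assert layout.tag(ax, ay) == "A5"
    assert layout.tag(1.0, 1.0) == "OUT"


def test_tagging_edges_follow_half_open_convention(layout):
    x0, y0, x1, y1 = layout.matrix_cells[(1, 1)]
    assert layout.tag(x0, y0) == "M11"  # closed lower edge
    assert layout.tag(x1, y0) != "M11"  # open upper edge belongs elsewhere


def test_filter_drops_first_then_outside_then_short(layout):
    trial = make_trial_frame(
        layout,
        "p1",
        "t01",
        0,
        [("M00", 0, 120), ("M01", 200, 90), ("M02", 400, 150), ("M10", 600, 200)],
    )
    sp = filter_trial(tag_fixations(trial, layout))
    assert list(sp.fixations["duration_ms"]) == [150.0, 200.0]


def test_first_fixation_dropped_even_when_valid(layout):
    trial = make_trial_frame(
        layout, "p1", "t01", 0, [("M00", i * 200, 150) for i in range(5)]
    )
    sp = filter_trial(tag_fixations(trial, layout))
    assert len(sp.fixations) == 4


def test_all_outside_trial_is_empty_not_error(layout):
    trial = make_trial_frame(layout, "p1", "t01", 0, [("OUT", 0, 150), ("OUT", 200, 150)])
    sp = filter_trial(tag_fixations(trial, layout))
    assert sp.empty
    assert sp.dwell_ms == {}


def test_strict_threshold_flag(layout):
    trial = make_trial_frame(
        layout, "p1", "t01", 0, [("OUT", 0, 100), ("M00", 200, 100), ("M01", 400, 101)]
    )
    tagged = tag_fixations(trial, layout)
    assert len(filter_trial(tagged).fixations) == 2
    assert len(filter_trial(tagged, strict_threshold=True).fixations) == 1


def test_filtering_is_idempotent(layout):
    trial = make_trial_frame(
        layout,
        "p1",
        "t01",
        0,
        [("OUT", 0, 300), ("M00", 400, 150), ("A1", 600, 90), ("A2", 800, 250)],
    )
    once = filter_trial(tag_fixations(trial, layout))
    twice = filter_trial(once.fixations, drop_first=False)
    pd.testing.assert_frame_equal(once.fixations, twice.fixations)
    assert once.dwell_ms == twice.dwell_ms


def test_dwell_never_exceeds_trial_duration(layout):
    rng = np.random.default_rng(3)
    for _ in range(20):
        events = [("OUT", 0, 200)]
        onset = 300
        for _ in range(int(rng.integers(2, 12))):
            label = rng.choice(["M00", "M11", "A0", "A4", "OUT"])
            dur = float(rng.integers(50, 400))
            events.append((label, onset, dur))
            onset += dur + 30
        sp = filter_trial(tag_fixations(make_trial_frame(layout, "p", "t", 0, events), layout))
        if not sp.empty:
            assert sum(sp.dwell_ms.values()) <= sp.trial_duration_ms + 1e-9


def test_vectorized_filtering_matches_per_trial(layout):
    """filter_fixations must agree with filter_trial applied trial by trial."""
    study = simulate_study(SyntheticConfig(n_participants=3, n_trials=4, seed=9))
    tagged = tag_fixations(study.fixations, study.layout)
    fast = filter_fixations(tagged, study.keys)
    for sp in fast:
        trial = tagged[
            (tagged["participant_id"] == sp.participant_id)
            & (tagged["trial_id"] == sp.trial_id)
        ]
        slow = filter_trial(trial)
        assert list(slow.fixations["onset_ms"]) == list(sp.fixations["onset_ms"])
        assert slow.dwell_ms == sp.dwell_ms


def _uniform_scanpaths(layout, spec):
    """spec: {pid: (n_trials, fixations_per_trial)} -> filtered scanpaths."""
    out = []
    for pid, (n_trials, n_fix) in spec.items():
        for t in range(n_trials):
            events = [("OUT", 0, 200)] + [
                ("M00", 300 + i * 200, 150) for i in range(n_fix)
            ]
            frame = make_trial_frame(layout, pid, f"t{t:02d}", t, events)
            out.append(filter_trial(tag_fixations(frame, layout)))
    return out


def test_low_fixation_count_excluded(layout):
    sps = _uniform_scanpaths(layout, {"sparse": (6, 2), "dense": (6, 8)})
    report = qc_participants(sps)
    assert report.retained == ["dense"]
    assert "low fixation count" in report.reasons("sparse")


def test_validity_ratio_boundary(layout):
    # 49 of 100 trials non-empty -> ratio 0.49 < 0.50 -> excluded
    sps = _uniform_scanpaths(layout, {"ok": (4, 8)})
    bad = _uniform_scanpaths(layout, {"patchy": (49, 8)})
    for t in range(51):
        frame = make_trial_frame(layout, "patchy", f"e{t:02d}", 100 + t, [("OUT", 0, 200), ("OUT", 300, 150)])
        bad.append(filter_trial(tag_fixations(frame, layout)))
    report = qc_participants(sps + bad, min_fix_per_trial=0)
    assert "patchy" not in report.retained
    assert "low validity ratio" in report.reasons("patchy")


def test_identical_scores_cause_no_sd_exclusions(layout):
    sps = _uniform_scanpaths(layout, {"a": (4, 8), "b": (4, 8), "c": (4, 8)})
    scores = pd.DataFrame({"participant_id": ["a", "b", "c"], "wm": [50.0, 50.0, 50.0]})
    report = qc_participants(sps, scores)
    assert report.retained == ["a", "b", "c"]


def test_score_outlier_excluded_with_reason(layout):
    spec = {f"s{i}": (4, 8) for i in range(12)}
    sps = _uniform_scanpaths(layout, spec)
    vals = [50.0] * 11 + [50.0 + 1e3]
    rng = np.random.default_rng(0)
    vals[:11] = list(50 + rng.normal(0, 1, 11))
    scores = pd.DataFrame({"participant_id": list(spec), "wm": vals})
    report = qc_participants(sps, scores)
    assert "s11" not in report.retained
    assert "score outlier (wm)" in report.reasons("s11")


def test_qc_invariant_to_participant_order(layout):
    sps = _uniform_scanpaths(layout, {"a": (4, 8), "b": (4, 2), "c": (4, 8)})
    fwd = qc_participants(sps)
    rev = qc_participants(list(reversed(sps)))
    assert fwd.retained == rev.retained
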
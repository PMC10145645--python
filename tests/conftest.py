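import numpy as np
import pandas as pd
import pytest

from gazestrat.io import ItemKey, default_layout
from gazestrat.preprocess import filter_trial, tag_fixations
from gazestrat.synth import SyntheticConfig, simulate_study, write_study


@pytest.fixture(scope="session")
def layout():
    return default_layout()


def rect_center(rect):
    x0, y0, x1, y1 = rect
    return (x0 + x1) / 2.0, (y0 + y1) / 2.0


def make_trial_frame(layout, participant_id, trial_id, trial_index, events):
    """Build a raw fixation frame from (aoi_label, onset, duration) triples.

    ``aoi_label`` is 'M{r}{c}', 'A{k}' or 'OUT'; positions are placed at the
    AOI centre (or off-screen corner for OUT).
    """
    rows = []
    for label, onset, duration in events:
        if label == "OUT":
            x, y = 3.0, 3.0
        elif label.startswith("M"):
            x, y = rect_center(layout.matrix_cells[(int(label[1]), int(label[2]))])
        else:
            x, y = rect_center(layout.answer_choices[int(label[1])])
        rows.append(
            {
                "participant_id": participant_id,
                "trial_id": trial_id,
                "trial_index": trial_index,
                "onset_ms": float(onset),
                "duration_ms": float(duration),
                "x_px": x,
                "y_px": y,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def hand_participant(layout):
    """Two fully hand-specified trials whose 14 metrics are known exactly.

    Each trial starts with an off-AOI fixation (dropped as the first raw
    fixation) and trial 1 carries one sub-threshold fixation (dropped by the
    duration filter).
    """
    keys = [
        ItemKey("t01", correct_choice=3),
        ItemKey("t02", correct_choice=0),
    ]
    t1 = make_trial_frame(
        layout,
        "p1",
        "t01",
        0,
        [
            ("OUT", 0, 900),  # first raw fixation: always dropped
            ("M00", 1000, 200),
            ("M00", 1300, 150),
            ("M01", 1500, 180),
            ("M02", 1690, 90),  # sub-threshold: dropped
            ("A3", 1700, 120),
            ("A2", 1900, 250),
            ("M22", 2200, 300),
        ],
    )
    t2 = make_trial_frame(
        layout,
        "p1",
        "t02",
        1,
        [
            ("M11", 0, 400),  # first raw fixation, in-AOI: still dropped
            ("M11", 500, 140),
            ("A0", 700, 110),
            ("A0", 850, 130),
            ("M11", 1000, 160),
        ],
    )
    tagged = [tag_fixations(t, layout) for t in (t1, t2)]
    scanpaths = [filter_trial(t) for t in tagged]
    return scanpaths, keys


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused by pipeline-level tests."""
    return simulate_study(SyntheticConfig(n_participants=16, n_trials=10, seed=5))


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory, small_study):
    """The small study written to disk in the interchange formats."""
    out = tmp_path_factory.mktemp("bundle")
    paths = write_study(small_study, out)
    return paths, small_study
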
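"""Tabular I/O for fixation events, AOI layouts, item keys and result tables.

The canonical in-memory containers are pandas DataFrames with fixed column
names; tracker exports with different headers are mapped through a *dialect*
(a ``canonical -> file column`` name map).  Layouts and item keys travel as
YAML or JSON; every emitted table is plain CSV/TSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

#: canonical fixation-table columns, in canonical order
FIXATION_COLUMNS = (
    "participant_id",
    "trial_id",
    "trial_index",
    "onset_ms",
    "duration_ms",
    "x_px",
    "y_px",
)

_NUMERIC_FIXATION_COLUMNS = ("trial_index", "onset_ms", "duration_ms", "x_px", "y_px")

#: default dialect: file columns already carry the canonical names
DEFAULT_DIALECT: dict[str, str] = {c: c for c in FIXATION_COLUMNS}


class FormatError(ValueError):
    """A file does not conform to the declared dialect or schema."""


class LayoutError(ValueError):
    """An AOI layout or item key fails validation."""


Rect = tuple[float, float, float, float]  # (x0, y0, x1, y1), half-open


def _rects_overlap(a: Rect, b: Rect) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


@dataclass(frozen=True)
class AoiLayout:
    """Screen geometry of the 3x3 problem matrix and the 2x4 answer bank.

    Rectangles are half-open ``[x0, x1) x [y0, y1)`` in screen pixels with the
    origin at the top-left, so a point on a shared edge belongs to exactly one
    rectangle (or to none).
    """

    matrix_cells: dict[tuple[int, int], Rect]
    answer_choices: dict[int, Rect]
    screen_size: tuple[int, int] = (1280, 1024)

    def __post_init__(self) -> None:
        if set(self.matrix_cells) != {(r, c) for r in range(3) for c in range(3)}:
            raise LayoutError(
                f"expected 9 matrix cells indexed (0..2, 0..2), got {sorted(self.matrix_cells)}"
            )
        if set(self.answer_choices) != set(range(8)):
            raise LayoutError(
                f"expected 8 answer choices indexed 0..7, got {sorted(self.answer_choices)}"
            )
        w, h = self.screen_size
        named = [(f"M{r}{c}", rect) for (r, c), rect in sorted(self.matrix_cells.items())]
        named += [(f"A{k}", rect) for k, rect in sorted(self.answer_choices.items())]
        for name, (x0, y0, x1, y1) in named:
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise LayoutError(f"rectangle {name} {(x0, y0, x1, y1)} outside screen {w}x{h}")
        for i, (na, ra) in enumerate(named):
            for nb, rb in named[i + 1 :]:
                if _rects_overlap(ra, rb):
                    raise LayoutError(f"rectangles overlap: {na} and {nb}")

    def tag(self, x: float, y: float) -> str:
        """AOI label of a point: ``'M{r}{c}'``, ``'A{k}'`` or ``'OUT'``."""
        for (r, c), (x0, y0, x1, y1) in self.matrix_cells.items():
            if x0 <= x < x1 and y0 <= y < y1:
                return f"M{r}{c}"
        for k, (x0, y0, x1, y1) in self.answer_choices.items():
            if x0 <= x < x1 and y0 <= y < y1:
                return f"A{k}"
        return "OUT"


@dataclass(frozen=True)
class ItemKey:
    """Correct answer choice of one test item."""

    trial_id: str
    correct_choice: int
    is_practice: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.correct_choice <= 7:
            raise LayoutError(
                f"item {self.trial_id!r}: correct_choice {self.correct_choice} not in 0..7"
            )


def default_layout(screen_size: tuple[int, int] = (1280, 1024)) -> AoiLayout:
    """A plausible WMT-2-like display: 3x3 matrix left, 2x4 answer bank right.

    The true stimulus pixel geometry is not public; this stand-in keeps the
    matrix/answer left-right arrangement and non-overlapping, in-bounds cells.
    """
    w, h = screen_size
    cell = int(w * 0.13)
    gap = int(w * 0.01)
    mx0, my0 = int(w * 0.06), int((h - 3 * cell - 2 * gap) / 2)
    matrix = {
        (r, c): (
            float(mx0 + c * (cell + gap)),
            float(my0 + r * (cell + gap)),
            float(mx0 + c * (cell + gap) + cell),
            float(my0 + r * (cell + gap) + cell),
        )
        for r in range(3)
        for c in range(3)
    }
    aw, ah = int(w * 0.085), int(w * 0.085)
    ax0 = int(w * 0.58)
    ay0 = int((h - 2 * ah - gap) / 2)
    answers = {
        k: (
            float(ax0 + (k % 4) * (aw + gap)),
            float(ay0 + (k // 4) * (ah + gap)),
            float(ax0 + (k % 4) * (aw + gap) + aw),
            float(ay0 + (k // 4) * (ah + gap) + ah),
        )
        for k in range(8)
    }
    return AoiLayout(matrix_cells=matrix, answer_choices=answers, screen_size=screen_size)


def read_fixation_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    trial_relative: bool = True,
) -> pd.DataFrame:
    """Read a fixation-report CSV/TSV into the canonical fixation table.

    Parameters
    ----------
    path
        CSV or TSV file with one row per fixation event.
    dialect
        ``canonical -> file column`` name map; defaults to canonical names.
    sep
        Field separator; inferred from the file extension when None.
    trial_relative
        When False, onsets are absolute timestamps and are re-based by
        subtracting each (participant, trial) group's earliest onset.

    Returns
    -------
    DataFrame sorted by (participant_id, trial_index, onset_ms) with the
    canonical columns; the input row count is preserved.
    """
    path = Path(path)
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [dialect[c] for c in FIXATION_COLUMNS if dialect.get(c, c) not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mapped column(s) {missing}")
    df = raw.rename(columns={v: k for k, v in dialect.items()})[list(FIXATION_COLUMNS)].copy()
    for col in _NUMERIC_FIXATION_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(f"{path.name}: non-numeric {col!r} at line {line}")
        df[col] = parsed
    if (df["duration_ms"] < 0).any():
        raise FormatError(f"{path.name}: negative duration_ms")
    if (df["onset_ms"] < 0).any() and trial_relative:
        raise FormatError(f"{path.name}: negative onset_ms in trial-relative mode")
    df["trial_index"] = df["trial_index"].astype(int)
    if not trial_relative:
        df["onset_ms"] -= df.groupby(["participant_id", "trial_id"])["onset_ms"].transform("min")
    df = df.sort_values(
        ["participant_id", "trial_index", "onset_ms"], kind="stable"
    ).reset_index(drop=True)
    return df


def load_aoi_layout(path: str | Path) -> tuple[AoiLayout, list[ItemKey]]:
    """Load an AOI layout plus per-item answer keys from YAML or JSON.

    Expected document shape::

        screen_size: [1280, 1024]
        matrix_cells: {"0,0": [x0, y0, x1, y1], ...}   # 9 entries
        answer_choices: {"0": [x0, y0, x1, y1], ...}   # 8 entries
        items: [{trial_id: t01, correct_choice: 3, is_practice: false}, ...]
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    try:
        cells = {
            tuple(int(p) for p in key.split(",")): tuple(float(v) for v in rect)
            for key, rect in doc["matrix_cells"].items()
        }
        answers = {int(k): tuple(float(v) for v in rect) for k, rect in doc["answer_choices"].items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path.name}: malformed layout document ({exc})") from exc
    layout = AoiLayout(
        matrix_cells=cells,
        answer_choices=answers,
        screen_size=tuple(doc.get("screen_size", (1280, 1024))),
    )
    keys = [
        ItemKey(
            trial_id=str(item["trial_id"]),
            correct_choice=int(item["correct_choice"]),
            is_practice=bool(item.get("is_practice", False)),
        )
        for item in doc.get("items", [])
    ]
    return layout, keys


def dump_aoi_layout(layout: AoiLayout, keys: Sequence[ItemKey], path: str | Path) -> None:
    """Inverse of :func:`load_aoi_layout` (YAML or JSON by extension)."""
    path = Path(path)
    doc = {
        "screen_size": list(layout.screen_size),
        "matrix_cells": {f"{r},{c}": list(rect) for (r, c), rect in sorted(layout.matrix_cells.items())},
        "answer_choices": {str(k): list(rect) for k, rect in sorted(layout.answer_choices.items())},
        "items": [
            {"trial_id": k.trial_id, "correct_choice": k.correct_choice, "is_practice": k.is_practice}
            for k in keys
        ],
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def write_table(records: pd.DataFrame, path: str | Path, format: str | None = None) -> Path:
    """Write a result table as csv, tsv or json (records orientation).

    Floats are written with ``repr`` round-trip precision so that
    ``read(write(x))`` reproduces ``x`` field for field.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".json": "json"}.get(path.suffix.lower(), "csv")
    if format == "csv":
        records.to_csv(path, index=False)
    elif format == "tsv":
        records.to_csv(path, index=False, sep="\t")
    elif format == "json":
        path.write_text(records.to_json(orient="records", indent=1, double_precision=15))
    else:
        raise ValueError(f"unknown table format {format!r}")
    return path


def read_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".json": "json"}.get(path.suffix.lower(), "csv")
    if format == "csv":
        return pd.read_csv(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.read_json(path, orient="records")
    raise ValueError(f"unknown table format {format!r}")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a participant x score table; one row per participant required."""
    df = read_table(path)
    if "participant_id" not in df.columns:
        raise FormatError(f"{Path(path).name}: score table lacks 'participant_id'")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise FormatError(f"score table has duplicate participant {dup!r}")
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    return df
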
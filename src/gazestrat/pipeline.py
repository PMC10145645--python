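"""End-to-end study analysis: read -> QC -> filter -> metrics -> clusters ->
models -> correlation comparisons -> descriptives, from one config.

Every stage is a pure function of (inputs, config, seed); rerunning the same
configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import corr as cc
from . import io as gio
from . import metrics as gm
from . import model as gmodel
from . import preprocess as pp

log = logging.getLogger("gazestrat")

#: default metric set for the dependent-correlation comparisons
HYPOTHESIS_METRICS = (
    "matrix_answer_time_ratio",
    "n_ma_transitions",
    "visits_per_wrong_answer",
)


@dataclass
class StudyConfig:
    """One study analysis run."""

    fixations: str
    layout: str
    scores: str
    out_dir: str
    min_fixation_ms: float = 100.0
    valid_ratio_min: float = 0.50
    min_fix_per_trial: float = 3.0
    score_sd_limit: float = 3.0
    cluster_restarts: int = 25
    model_targets: list[str] | None = None
    steiger_metrics: list[str] = field(default_factory=lambda: list(HYPOTHESIS_METRICS))
    train_fraction: float = 0.8
    seed: int = 0
    dialect: dict[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def describe(table: pd.DataFrame) -> pd.DataFrame:
    """Moment descriptives per numeric column.

    Skewness and excess kurtosis use the bias-corrected sample estimators
    (normal data -> both near 0); constant columns report them as missing.
    """
    rows = []
    for col in table.select_dtypes("number").columns:
        vals = table[col].dropna()
        if len(vals) < 3:
            raise ValueError(f"column {col!r} has fewer than 3 values")
        constant = float(vals.std(ddof=1)) == 0.0
        rows.append(
            {
                "variable": col,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "skewness": np.nan if constant else float(vals.skew()),
                "kurtosis": np.nan if constant else float(vals.kurt()),
                "note": "constant column" if constant else "",
            }
        )
    return pd.DataFrame(rows)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def run_study(config: StudyConfig) -> dict:
    """Run the full analysis; returns the report bundle (paths + key frames)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    # manifest records names relative to out_dir so identical runs into
    # different directories stay byte-identical
    def _save(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        gio.write_table(frame, path)
        manifest[name] = path.name

    try:
        stage = "read"
        fixations = gio.read_fixation_table(config.fixations, dialect=config.dialect)
        layout, keys = gio.load_aoi_layout(config.layout)
        scores = gio.read_score_table(config.scores)
        n_read = fixations["participant_id"].nunique()
        log.info("read %d fixations from %d participants", len(fixations), n_read)

        stage = "filter"
        tagged = pp.tag_fixations(fixations, layout)
        scanpaths = pp.filter_fixations(tagged, keys, min_duration_ms=config.min_fixation_ms)

        stage = "qc"
        qc = pp.qc_participants(
            scanpaths,
            scores,
            valid_ratio_min=config.valid_ratio_min,
            min_fix_per_trial=config.min_fix_per_trial,
            score_sd_limit=config.score_sd_limit,
        )
        for row in qc.table.itertuples():
            if row.excluded:
                log.info("excluded %s: %s", row.participant_id, row.reason)
        _save("qc_report", qc.table)
        retained = set(qc.retained)
        scanpaths = [s for s in scanpaths if s.participant_id in retained]

        stage = "cluster"
        usable = [s for s in scanpaths if not s.empty]
        feats = np.vstack(
            [cl.build_transition_features(gm.collapse_aoi_sequence(s)) for s in usable]
        )
        model = cl.ScanpathKMeans(
            n_restarts=config.cluster_restarts, random_state=config.seed
        ).fit(feats)
        labels = {
            (s.participant_id, s.trial_id): int(lab) for s, lab in zip(usable, model.labels_)
        }
        label_frame = pd.DataFrame(
            [
                {"participant_id": p, "trial_id": t, "cluster": lab}
                for (p, t), lab in labels.items()
            ]
        )
        _save("trial_labels", label_frame)
        for lab in (1, 2):
            mat = model.centroid_matrix(lab).reset_index(names="from_aoi")
            _save(f"centroid_cluster{lab}", mat)

        stage = "metrics"
        metrics = gm.participant_metrics_table(scanpaths, keys, cluster_labels=labels)
        _save("metrics", metrics)

        stage = "cluster_contrasts"
        trial_metrics = cl.trial_metric_table(usable, keys)
        _save("cluster_contrasts", cl.cluster_comparison_table(trial_metrics, model.labels_))

        stage = "models"
        targets = config.model_targets
        if targets is None:
            targets = [c for c in scores.columns if c != "participant_id"]
        unknown = [t for t in targets if t not in scores.columns]
        if unknown:
            raise ValueError(f"unknown model target(s): {unknown}")
        model_reports = {}
        for i, target in enumerate(targets):
            report = gmodel.run_lasso_analysis(
                metrics,
                scores,
                target,
                train_fraction=config.train_fraction,
                seed=config.seed + 1000 * (i + 1),
            )
            model_reports[target] = report
            path = out / f"model_{target}.json"
            _dump_json(report, path)
            manifest[f"model_{target}"] = path.name

        stage = "correlations"
        joined = metrics.merge(scores, on="participant_id")
        variables = [c for c in gm.METRIC_COLUMNS if metrics[c].notna().any()] + targets
        corr = cc.pearson_matrix(joined[variables].dropna())
        n_corr = len(joined[variables].dropna())
        _save("correlation_matrix", corr.reset_index(names="variable"))
        steiger_metrics = [m for m in config.steiger_metrics if m in corr.index]
        _save("steiger_tests", cc.steiger_table(corr, n_corr, steiger_metrics, targets))
        _save("forest_data", cc.forest_table(corr, n_corr, steiger_metrics, targets))

        stage = "descriptives"
        _save("descriptives", describe(joined[variables]))

        stage = "manifest"
        summary = {
            "n_participants_read": int(n_read),
            "n_participants_retained": len(qc.retained),
            "n_participants_excluded": int(qc.table["excluded"].sum()),
            "n_scored_trials": int(len(usable)),
            "seed": config.seed,
            "thresholds": {
                "min_fixation_ms": config.min_fixation_ms,
                "valid_ratio_min": config.valid_ratio_min,
                "min_fix_per_trial": config.min_fix_per_trial,
                "score_sd_limit": config.score_sd_limit,
            },
            "outputs": manifest,
        }
        _dump_json(summary, out / "run_summary.json")
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        _dump_json({"failed_stage": stage, "outputs": manifest}, out / "run_summary.json")
        raise StageError(stage, exc) from exc

    return {
        "summary": summary,
        "qc": qc,
        "metrics": metrics,
        "cluster_model": model,
        "trial_labels": label_frame,
        "model_reports": model_reports,
        "correlations": corr,
        "out_dir": str(out),
    }
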
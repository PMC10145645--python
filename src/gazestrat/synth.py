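"""Synthetic matrix-reasoning gaze studies with planted strategy structure.

The generator emulates the statistical structure the analysis assumes, so the
whole pipeline is exercisable with no external data:

* two latent scanpath strategies realized as first-order Markov kernels over
  the 10 clustering AOIs — a *constructive* kernel that walks the matrix
  strictly row-by-row and enters the answer bank almost only after the bottom
  row, and a *hybrid* kernel mixing row-wise and column-wise moves with
  elevated answer entries from the end of every row;
* per-participant strategy propensity (Beta-distributed probability of using
  the hybrid kernel on a given trial);
* negative-binomial chain lengths, lognormal fixation durations per AOI side
  (floored at the recorder minimum), and a configurable contamination
  fraction of sub-threshold / off-AOI fixations to exercise the filters;
* cognitive scores generated as noisy linear functions of the participant's
  true gaze metrics, with the noise solved to hit a target signal R^2.

Every random draw flows from one seeded generator, so a fixed master seed
gives byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import CLUSTER_AOIS
from .io import AoiLayout, ItemKey, default_layout, dump_aoi_layout, write_table
from .metrics import METRIC_COLUMNS, participant_metrics_table
from .preprocess import filter_fixations, tag_fixations

_ANS = 9  # index of the pooled answer AOI in CLUSTER_AOIS


@dataclass
class StrategyKernel:
    """A first-order Markov scanpath strategy over the 10 clustering AOIs."""

    name: str
    transition: np.ndarray  # (10, 10), rows sum to 1, zero diagonal
    initial: np.ndarray  # (10,)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (10, 10):
            raise ValueError("transition matrix must be 10x10")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if np.any(np.diag(self.transition) != 0.0):
            raise ValueError("self-transitions are not representable (diagonal must be 0)")
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")

    @property
    def answer_entry_mass(self) -> float:
        """Mean probability of moving into the answer region from a matrix cell."""
        return float(self.transition[:_ANS, _ANS].mean())


def _normalize_rows(w: np.ndarray) -> np.ndarray:
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def constructive_kernel() -> StrategyKernel:
    """Row-wise scanning; answer entries almost only after the bottom row."""
    w = np.full((10, 10), 0.05)
    for cell in range(9):
        r, c = divmod(cell, 3)
        if cell + 1 <= 8:  # next cell in reading order
            w[cell, cell + 1 if c < 2 else 3 * (r + 1)] = 8.0
        if cell - 1 >= 0:  # step back
            w[cell, cell - 1] = 1.0
        if cell == 8:
            w[cell, _ANS] = 6.0
        elif c == 2:
            w[cell, _ANS] = 0.4
        else:
            w[cell, _ANS] = 0.1
    w[_ANS, :] = 0.3
    w[_ANS, 0] = 4.0  # return to the top-left to re-inspect
    init = np.full(10, 0.15)
    init[0], init[1], init[_ANS] = 8.0, 1.0, 0.05
    return StrategyKernel("constructive", _normalize_rows(w), init / init.sum())


def hybrid_kernel() -> StrategyKernel:
    """Row- and column-wise scanning; answer entries from the end of any row."""
    w = np.full((10, 10), 0.1)
    for cell in range(9):
        r, c = divmod(cell, 3)
        if c < 2:
            w[cell, cell + 1] = 4.0  # along the row
        if r < 2:
            w[cell, cell + 3] = 3.0  # down the column
        if c > 0:
            w[cell, cell - 1] = 1.0
        if r > 0:
            w[cell, cell - 3] = 0.5
        w[cell, _ANS] = 3.0 if c == 2 else 0.5
    w[_ANS, :] = 0.7
    w[_ANS, 0] = 2.0
    init = np.full(10, 0.4)
    init[0], init[_ANS] = 5.0, 0.1
    return StrategyKernel("hybrid", _normalize_rows(w), init / init.sum())


def kernel_pair(separability: float = 1.0) -> tuple[StrategyKernel, StrategyKernel]:
    """The constructive kernel and a hybrid kernel pulled toward it.

    ``separability`` in [0, 1] linearly interpolates the hybrid kernel
    between the constructive one (0: both strategies identical, clustering
    can only recover chance) and the fully distinct hybrid portrait (1).
    """
    if not 0.0 <= separability <= 1.0:
        raise ValueError("separability must lie in [0, 1]")
    cons, hyb = constructive_kernel(), hybrid_kernel()
    mixed = StrategyKernel(
        "hybrid",
        (1 - separability) * cons.transition + separability * hyb.transition,
        (1 - separability) * cons.initial + separability * hyb.initial,
    )
    return cons, mixed


@dataclass
class ScoreModel:
    """One cognitive score as a noisy linear function of true gaze metrics."""

    beta: dict[str, float]  # metric name -> coefficient on z-scored metrics
    target_r2: float = 0.6
    noise_sd: float | None = None  # overrides target_r2 when set


def default_score_models() -> dict[str, ScoreModel]:
    """Study-like score battery: one strong multi-metric score, two weaker ones."""
    return {
        "reasoning": ScoreModel(
            beta={
                "n_ma_transitions": 0.6,
                "matrix_answer_time_ratio": 0.6,
                "visits_per_wrong_answer": -0.6,
            },
            target_r2=0.6,
        ),
        "working_memory": ScoreModel(beta={"n_ma_transitions": -0.5}, target_r2=0.25),
        "planning": ScoreModel(beta={"matrix_answer_time_ratio": 0.45}, target_r2=0.2),
    }


@dataclass
class SyntheticConfig:
    """Study conditions of the generator (defaults are the tested conditions)."""

    n_participants: int = 60
    n_trials: int = 18
    n_practice: int = 3
    propensity_alpha: float = 2.0  # Beta prior on per-participant hybrid propensity
    propensity_beta: float = 2.0
    steps_mean: float = 22.0  # negative-binomial AOI-chain length per trial
    steps_dispersion: float = 20.0
    min_steps: int = 4
    matrix_dur_median_ms: float = 260.0
    answer_dur_median_ms: float = 230.0
    dur_sigma: float = 0.30  # lognormal sigma of fixation durations
    min_duration_ms: float = 100.0
    extra_fix_matrix: float = 0.8  # Poisson extra fixations per matrix-cell visit
    extra_fix_answer: float = 0.4
    answer_run_mean: float = 0.8  # Poisson extra answer choices per answer episode
    # Individual-difference spreads. Real cohorts differ in answer-checking
    # style, revisiting habits and fixation tempo over and above their
    # strategy mix; these give each metric family variance of its own rather
    # than deriving everything from one latent strategy driver.
    # per-participant preference for fixating the correct choice (Beta, mean 0.35)
    p_correct_alpha: float = 1.05
    p_correct_beta: float = 1.95
    # per-participant lognormal tempo multipliers on the duration medians,
    # one per AOI side: individual dwell-speed differences
    tempo_sigma: float = 0.4
    # per-participant lognormal multiplier on the answer-episode run length
    answer_run_sigma: float = 0.5
    # per-participant lognormal multiplier on the chain length (session pace)
    steps_sigma: float = 0.0
    # per-participant lognormal multiplier on the extra-fixation rates;
    # separates fixation counts from visit counts
    extra_fix_sigma: float = 0.6
    # per-participant lognormal multiplier on the kernels' answer-entry
    # probabilities: answer-checking frequency varies within either strategy
    ans_entry_sigma: float = 0.3
    saccade_gap_ms: float = 30.0
    contamination: float = 0.05  # fraction of sub-threshold / off-AOI fixations
    separability: float = 1.0
    score_models: dict[str, ScoreModel] = field(default_factory=default_score_models)
    seed: int | None = None


@dataclass
class GroundTruth:
    """Planted quantities aligned with the emitted tables."""

    trial_strategies: pd.DataFrame  # participant_id, trial_id, strategy
    propensity: pd.DataFrame  # participant_id, p_hybrid
    true_metrics: pd.DataFrame  # metrics recomputed from the emitted fixations
    noiseless_scores: pd.DataFrame


@dataclass
class SyntheticStudy:
    """A complete simulated study bundle."""

    fixations: pd.DataFrame
    layout: AoiLayout
    keys: list[ItemKey]
    scores: pd.DataFrame
    ground_truth: GroundTruth
    config: SyntheticConfig


@dataclass
class ParticipantEffects:
    """Individual-difference multipliers applied to every trial of one person."""

    p_correct: float = 0.35  # probability an answer fixation targets the correct choice
    matrix_tempo: float = 1.0  # multiplier on the matrix-side duration median
    answer_tempo: float = 1.0
    answer_run_mult: float = 1.0  # multiplier on the answer-episode run length
    steps_mult: float = 1.0  # multiplier on the AOI-chain length
    extra_fix_mult: float = 1.0  # multiplier on the extra-fixation rates
    ans_entry_mult: float = 1.0  # multiplier on kernel answer-entry probabilities

    @classmethod
    def draw(cls, cfg: "SyntheticConfig", rng: np.random.Generator) -> "ParticipantEffects":
        return cls(
            p_correct=float(rng.beta(cfg.p_correct_alpha, cfg.p_correct_beta)),
            matrix_tempo=float(rng.lognormal(0.0, cfg.tempo_sigma)),
            answer_tempo=float(rng.lognormal(0.0, cfg.tempo_sigma)),
            answer_run_mult=float(rng.lognormal(0.0, cfg.answer_run_sigma)),
            steps_mult=float(rng.lognormal(0.0, cfg.steps_sigma)),
            extra_fix_mult=float(rng.lognormal(0.0, cfg.extra_fix_sigma)),
            ans_entry_mult=float(rng.lognormal(0.0, cfg.ans_entry_sigma)),
        )


def personalize_kernel(kernel: StrategyKernel, ans_entry_mult: float) -> StrategyKernel:
    """Scale a kernel's matrix-to-answer probabilities by one participant's
    answer-checking tendency, rescaling the within-matrix mass to compensate.
    """
    if ans_entry_mult == 1.0:
        return kernel
    t = kernel.transition.copy()
    for row in range(_ANS):
        p = t[row, _ANS]
        p_new = min(p * ans_entry_mult, 0.9)
        rest = 1.0 - p
        if rest > 0:
            t[row, :_ANS] *= (1.0 - p_new) / rest
        t[row, _ANS] = p_new
    return StrategyKernel(kernel.name, t, kernel.initial)


def _draw_steps(
    cfg: SyntheticConfig, rng: np.random.Generator, effects: "ParticipantEffects"
) -> int:
    mean = cfg.steps_mean * effects.steps_mult
    r = cfg.steps_dispersion
    p = r / (r + mean)
    return max(int(rng.negative_binomial(r, p)), cfg.min_steps)


def _duration(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    matrix_side: bool,
    effects: "ParticipantEffects",
) -> float:
    if matrix_side:
        median = cfg.matrix_dur_median_ms * effects.matrix_tempo
    else:
        median = cfg.answer_dur_median_ms * effects.answer_tempo
    d = float(rng.lognormal(np.log(median), cfg.dur_sigma))
    return max(d, cfg.min_duration_ms)


def _place(rect: tuple[float, float, float, float], rng: np.random.Generator) -> tuple[float, float]:
    x0, y0, x1, y1 = rect
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    x = float(np.clip(cx + rng.normal(0.0, (x1 - x0) / 8.0), x0 + 0.5, x1 - 0.5))
    y = float(np.clip(cy + rng.normal(0.0, (y1 - y0) / 8.0), y0 + 0.5, y1 - 0.5))
    return x, y


def _draw_choice(
    p_correct: float, rng: np.random.Generator, correct: int, avoid: int | None
) -> int:
    while True:
        if rng.random() < p_correct:
            choice = correct
        else:
            choice = int(rng.integers(0, 8))
        if choice != avoid:
            return choice


def simulate_trial(
    kernel: StrategyKernel,
    config: SyntheticConfig,
    rng: np.random.Generator,
    layout: AoiLayout,
    participant_id: str,
    trial_id: str,
    trial_index: int,
    correct_choice: int,
    effects: ParticipantEffects | None = None,
) -> pd.DataFrame:
    """Fixation rows of one trial driven by one strategy kernel.

    The first emitted fixation sits at the screen centre (the fixation-point
    carry-over that the preprocessing drops); each AOI-chain visit emits one
    or more fixations; answer-region entries are expanded into a short run of
    concrete answer choices.
    """
    effects = effects or ParticipantEffects()
    rows: list[dict] = []
    onset = 0.0

    def emit(aoi_label: str, x: float, y: float, duration: float) -> None:
        nonlocal onset
        if config.contamination > 0 and rng.random() < config.contamination:
            if rng.random() < 0.5:
                duration = float(rng.uniform(40.0, config.min_duration_ms - 1.0))
            else:
                x, y = float(rng.uniform(0, 40)), float(rng.uniform(0, 40))
        rows.append(
            {
                "participant_id": participant_id,
                "trial_id": trial_id,
                "trial_index": trial_index,
                "onset_ms": onset,
                "duration_ms": duration,
                "x_px": x,
                "y_px": y,
            }
        )
        onset += duration + config.saccade_gap_ms

    # carried-over fixation on the inter-trial fixation point (screen centre)
    w, h = layout.screen_size
    rows.append(
        {
            "participant_id": participant_id,
            "trial_id": trial_id,
            "trial_index": trial_index,
            "onset_ms": onset,
            "duration_ms": _duration(config, rng, True, effects),
            "x_px": w / 2.0,
            "y_px": h / 2.0,
        }
    )
    onset = rows[-1]["onset_ms"] + rows[-1]["duration_ms"] + config.saccade_gap_ms

    n_steps = _draw_steps(config, rng, effects)
    state = int(rng.choice(10, p=kernel.initial))
    prev_choice: int | None = None
    for _ in range(n_steps):
        if state < _ANS:
            r, c = divmod(state, 3)
            rect = layout.matrix_cells[(r, c)]
            for _ in range(1 + int(rng.poisson(config.extra_fix_matrix * effects.extra_fix_mult))):
                x, y = _place(rect, rng)
                emit(f"M{r}{c}", x, y, _duration(config, rng, True, effects))
            prev_choice = None
        else:
            n_choices = 1 + int(rng.poisson(config.answer_run_mean * effects.answer_run_mult))
            for _ in range(n_choices):
                choice = _draw_choice(effects.p_correct, rng, correct_choice, prev_choice)
                rect = layout.answer_choices[choice]
                for _ in range(
                    1 + int(rng.poisson(config.extra_fix_answer * effects.extra_fix_mult))
                ):
                    x, y = _place(rect, rng)
                    emit(f"A{choice}", x, y, _duration(config, rng, False, effects))
                prev_choice = choice
        state = int(rng.choice(10, p=kernel.transition[state]))
    return pd.DataFrame(rows)


def simulate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Simulate a full study bundle under ``config`` (defaults otherwise).

    Scores are built from the *true* metrics — the metric module re-applied
    to the emitted fixation table — with the cluster-share metric taken from
    the planted per-trial strategies; Gaussian noise is scaled so the linear
    signal explains ``target_r2`` of each score's variance in this sample.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    layout = default_layout()
    cons, hyb = kernel_pair(cfg.separability)

    keys = [
        ItemKey(trial_id=f"p{i + 1:02d}", correct_choice=int(rng.integers(0, 8)), is_practice=True)
        for i in range(cfg.n_practice)
    ] + [
        ItemKey(trial_id=f"t{i + 1:02d}", correct_choice=int(rng.integers(0, 8)), is_practice=False)
        for i in range(cfg.n_trials)
    ]
    correct = {k.trial_id: k.correct_choice for k in keys}

    frames: list[pd.DataFrame] = []
    strat_rows: list[dict] = []
    prop_rows: list[dict] = []
    for p in range(cfg.n_participants):
        pid = f"s{p + 1:03d}"
        prop = float(rng.beta(cfg.propensity_alpha, cfg.propensity_beta))
        prop_rows.append({"participant_id": pid, "p_hybrid": prop})
        effects = ParticipantEffects.draw(cfg, rng)
        cons_p = personalize_kernel(cons, effects.ans_entry_mult)
        hyb_p = personalize_kernel(hyb, effects.ans_entry_mult)
        for idx, key in enumerate(keys):
            use_hybrid = rng.random() < prop
            kernel = hyb_p if use_hybrid else cons_p
            frames.append(
                simulate_trial(
                    kernel, cfg, rng, layout, pid, key.trial_id, idx,
                    correct[key.trial_id], effects,
                )
            )
            if not key.is_practice:
                strat_rows.append(
                    {
                        "participant_id": pid,
                        "trial_id": key.trial_id,
                        "strategy": kernel.name,
                    }
                )
    fixations = pd.concat(frames, ignore_index=True)
    strategies = pd.DataFrame(strat_rows)

    # true metrics from the emitted data; cluster share from planted strategies
    tagged = tag_fixations(fixations, layout)
    scanpaths = filter_fixations(tagged, keys, min_duration_ms=cfg.min_duration_ms)
    planted = {
        (row.participant_id, row.trial_id): 2 if row.strategy == "hybrid" else 1
        for row in strategies.itertuples()
    }
    true_metrics = participant_metrics_table(scanpaths, keys, cluster_labels=planted)

    z = true_metrics.set_index("participant_id")[list(METRIC_COLUMNS)]
    z = (z - z.mean()) / z.std(ddof=1)
    score_rows = pd.DataFrame({"participant_id": z.index})
    noiseless = pd.DataFrame({"participant_id": z.index})
    for name, model in cfg.score_models.items():
        unknown = set(model.beta) - set(METRIC_COLUMNS)
        if unknown:
            raise ValueError(f"score {name!r}: unknown metric(s) {sorted(unknown)}")
        signal = sum(b * z[m].to_numpy() for m, b in model.beta.items())
        signal = np.asarray(signal, dtype=float)
        if model.noise_sd is not None:
            noise_sd = model.noise_sd
        else:
            r2 = model.target_r2
            if not 0.0 < r2 <= 1.0:
                raise ValueError(f"score {name!r}: target_r2 must be in (0, 1]")
            sd_sig = float(np.std(signal, ddof=1))
            noise_sd = sd_sig * np.sqrt((1.0 - r2) / r2) if r2 < 1.0 else 0.0
        noiseless[name] = signal
        score_rows[name] = signal + rng.normal(0.0, noise_sd, size=len(signal))

    truth = GroundTruth(
        trial_strategies=strategies,
        propensity=pd.DataFrame(prop_rows),
        true_metrics=true_metrics,
        noiseless_scores=noiseless,
    )
    return SyntheticStudy(
        fixations=fixations,
        layout=layout,
        keys=keys,
        scores=score_rows.reset_index(drop=True),
        ground_truth=truth,
        config=cfg,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the standard interchange formats.

    Emits ``fixations.csv``, ``layout.yaml`` (geometry + item keys),
    ``scores.csv`` and ``ground_truth.json``; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fixations": out / "fixations.csv",
        "layout": out / "layout.yaml",
        "scores": out / "scores.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_table(study.fixations, paths["fixations"])
    dump_aoi_layout(study.layout, study.keys, paths["layout"])
    write_table(study.scores, paths["scores"])
    gt = study.ground_truth
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "trial_strategies": gt.trial_strategies.to_dict(orient="records"),
                "propensity": gt.propensity.to_dict(orient="records"),
                "true_metrics": json.loads(gt.true_metrics.to_json(orient="records")),
                "noiseless_scores": json.loads(gt.noiseless_scores.to_json(orient="records")),
            },
            indent=1,
        )
    )
    return paths
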
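import numpy as np
import pandas as pd
import pytest

from gazestrat.io import default_layout
from gazestrat.preprocess import filter_fixations, tag_fixations
from gazestrat.synth import (
    ParticipantEffects,
    ScoreModel,
    StrategyKernel,
    SyntheticConfig,
    constructive_kernel,
    default_score_models,
    hybrid_kernel,
    kernel_pair,
    personalize_kernel,
    simulate_study,
    simulate_trial,
    write_study,
)


def test_kernels_are_valid_and_ordered():
    cons, hyb = constructive_kernel(), hybrid_kernel()
    for k in (cons, hyb):
        np.testing.assert_allclose(k.transition.sum(axis=1), 1.0)
        assert np.all(np.diag(k.transition) == 0.0)
    assert hyb.answer_entry_mass > cons.answer_entry_mass


def test_separability_interpolates_kernels():
    cons0, hyb0 = kernel_pair(0.0)
    np.testing.assert_allclose(cons0.transition, hyb0.transition)
    _, hyb1 = kernel_pair(1.0)
    np.testing.assert_allclose(hyb1.transition, hybrid_kernel().transition)
    with pytest.raises(ValueError):
        kernel_pair(1.5)


def test_invalid_kernel_rejected():
    bad = np.full((10, 10), 0.1)
    with pytest.raises(ValueError, match="diagonal"):
        StrategyKernel("x", bad, np.full(10, 0.1))


def test_personalized_kernel_scales_answer_entry():
    cons = constructive_kernel()
    boosted = personalize_kernel(cons, 1.5)
    np.testing.assert_allclose(boosted.transition.sum(axis=1), 1.0)
    assert boosted.answer_entry_mass > cons.answer_entry_mass


def test_degenerate_kernel_walks_deterministically():
    t = np.full((10, 10), 1 / 9)  # unvisited filler rows, valid but unused
    np.fill_diagonal(t, 0.0)
    for row, target in ((0, 1), (1, 9), (9, 0)):  # M00 -> M01 -> ANS -> M00
        t[row] = 0.0
        t[row, target] = 1.0
    init = np.zeros(10)
    init[0] = 1.0
    kernel = StrategyKernel("det", t, init)
    cfg = SyntheticConfig(
        steps_mean=3, steps_dispersion=1e6, min_steps=3, extra_fix_matrix=0.0,
        extra_fix_answer=0.0, answer_run_mean=0.0, contamination=0.0, seed=0,
    )
    rng = np.random.default_rng(0)
    layout = default_layout()
    frame = simulate_trial(kernel, cfg, rng, layout, "p", "t01", 0, correct_choice=2)
    tagged = tag_fixations(frame, layout)
    # first fixation is the screen-centre carry-over; the rest follow the chain
    assert list(tagged["aoi"])[1:] == ["M00", "M01", "A2"]


def test_empirical_transitions_match_kernel():
    """Observed 10-AOI transition frequencies agree with the chain kernel."""
    from gazestrat.cluster import CLUSTER_AOIS
    from gazestrat.metrics import collapse

    kernel = hybrid_kernel()
    cfg = SyntheticConfig(
        steps_mean=5000, steps_dispersion=1e9, min_steps=5000, extra_fix_matrix=0.0,
        extra_fix_answer=0.0, answer_run_mean=0.0, contamination=0.0,
    )
    rng = np.random.default_rng(42)
    layout = default_layout()
    frame = simulate_trial(kernel, cfg, rng, layout, "p", "t01", 0, correct_choice=0)
    tags = tag_fixations(frame, layout)["aoi"].tolist()[1:]
    idx = {a: i for i, a in enumerate(CLUSTER_AOIS)}
    pooled = collapse(["ANS" if t.startswith("A") else t for t in tags])
    counts = np.zeros((10, 10))
    for a, b in zip(pooled, pooled[1:]):
        counts[idx[a], idx[b]] += 1
    for i in range(10):
        n_row = counts[i].sum()
        assert n_row > 50
        for j in range(10):
            p = kernel.transition[i, j]
            se = np.sqrt(max(p * (1 - p), 1e-12) / n_row)
            assert abs(counts[i, j] / n_row - p) <= max(3 * se, 0.01)


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SyntheticConfig(n_participants=3, n_trials=4, seed=77)
    a = simulate_study(cfg)
    b = simulate_study(cfg)
    pd.testing.assert_frame_equal(a.fixations, b.fixations)
    pd.testing.assert_frame_equal(a.scores, b.scores)
    pa = write_study(a, tmp_path / "a")
    pb = write_study(b, tmp_path / "b")
    for name in pa:
        assert pa[name].read_bytes() == pb[name].read_bytes()


def test_zero_noise_scores_reproduce_linear_signal():
    models = default_score_models()
    models["reasoning"] = ScoreModel(beta=models["reasoning"].beta, noise_sd=0.0)
    study = simulate_study(SyntheticConfig(n_participants=8, n_trials=6, seed=3, score_models=models))
    np.testing.assert_allclose(
        study.scores["reasoning"], study.ground_truth.noiseless_scores["reasoning"], atol=1e-12
    )


def test_unknown_score_metric_rejected():
    models = {"bad": ScoreModel(beta={"not_a_metric": 1.0})}
    with pytest.raises(ValueError, match="unknown metric"):
        simulate_study(SyntheticConfig(n_participants=6, n_trials=4, seed=1, score_models=models))


def test_clean_output_passes_filters_unchanged():
    """Without contamination, only the first fixation of each trial is filtered."""
    study = simulate_study(SyntheticConfig(n_participants=3, n_trials=4, contamination=0.0, seed=13))
    tagged = tag_fixations(study.fixations, study.layout)
    sps = filter_fixations(tagged, study.keys)
    raw_scored = tagged[tagged["trial_id"].str.startswith("t")]
    n_trials = raw_scored.groupby(["participant_id", "trial_id"]).ngroups
    assert sum(len(s.fixations) for s in sps) == len(raw_scored) - n_trials


def test_practice_trials_flagged_and_excluded():
    study = simulate_study(SyntheticConfig(n_participants=2, n_trials=4, seed=2))
    practice = [k.trial_id for k in study.keys if k.is_practice]
    assert len(practice) == 3
    tagged = tag_fixations(study.fixations, study.layout)
    sps = filter_fixations(tagged, study.keys)
    assert not {s.trial_id for s in sps} & set(practice)


def test_ground_truth_aligns_with_fixations():
    study = simulate_study(SyntheticConfig(n_participants=4, n_trials=5, seed=6))
    gt = study.ground_truth
    scored = {k.trial_id for k in study.keys if not k.is_practice}
    assert len(gt.trial_strategies) == 4 * 5
    assert set(gt.trial_strategies["trial_id"]) == scored
    assert set(gt.trial_strategies["strategy"]) <= {"constructive", "hybrid"}
    assert list(gt.true_metrics["participant_id"]) == sorted(
        study.fixations["participant_id"].unique()
    )
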
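"""Multistage core: augmentation schema, stage loop, selection, inference."""

import numpy as np
import pytest

from paintriage import (
    BaseLearnerSpec,
    FeatureMatrix,
    MultistageTriage,
    StageProbabilities,
    augment,
    fit_multistage,
    run_stage,
)
from paintriage.learners import stratified_folds
from paintriage.model import LoadedChain, SchemaError


def _fm(n, d, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureMatrix(
        rng.normal(size=(n, d)), [f"x_{j}" for j in range(d)], ["structured"] * d
    )


def _sp(stage, probs):
    return StageProbabilities(stage_index=stage, probs=np.asarray(probs, float))


# ---------------------------------------------------------------------------
# augmentation

def test_augment_appends_named_column():
    X = _fm(8, 231)
    out = augment(X, [_sp(1, np.linspace(0, 1, 8))])
    assert out.n_features == 232
    assert out.feature_names[-1] == "stage_prob_1"
    assert out.feature_kind[-1] == "stage_prob"
    assert np.array_equal(out.values[:, :231], X.values)
    assert out.feature_names[:231] == X.feature_names


def test_augment_empty_history_is_identity():
    X = _fm(5, 4)
    assert augment(X, []) is X


def test_augment_mode_column_arithmetic():
    X = _fm(6, 5)
    hist = [_sp(1, np.zeros(6)), _sp(2, np.ones(6))]
    assert augment(X, hist, "cumulative").n_features == 7
    out = augment(X, hist, "last_only")
    assert out.n_features == 6
    assert out.feature_names[-1] == "stage_prob_2"


def test_augment_schema_arithmetic_all_stages():
    X = _fm(10, 9)
    hist = []
    for j in range(1, 5):
        assert augment(X, hist, "cumulative").n_features == 9 + (j - 1)
        hist.append(_sp(j, np.random.default_rng(j).random(10)))


def test_augment_length_mismatch():
    with pytest.raises(ValueError, match="entries"):
        augment(_fm(6, 3), [_sp(1, np.zeros(5))])


# ---------------------------------------------------------------------------
# stage running

def test_stage_on_separable_toy(separable_toy):
    X, y = separable_toy
    fm = FeatureMatrix(X, ["a", "b"], ["structured"] * 2)
    folds = stratified_folds(y, k=5, seed=0)
    res = run_stage(BaseLearnerSpec("easy_ensemble", seed=0), fm, y, folds)
    assert res.metrics.tpr == 1.0
    assert res.oof.provenance == "out_of_fold"


def test_oracle_feature_dominates_noise():
    """Stage 2 with y_1 equal to the label is perfect regardless of x noise."""
    rng = np.random.default_rng(3)
    y = np.array([1] * 10 + [0] * 40)
    fm = _fm(50, 6, seed=3)
    folds = stratified_folds(y, k=5, seed=0)
    X_aug = augment(fm, [_sp(1, y.astype(float))])
    res = run_stage(
        BaseLearnerSpec("easy_ensemble", seed=0), X_aug, y, folds, stage_index=2
    )
    assert res.metrics.tpr == 1.0
    assert res.metrics.tnr == 1.0


# ---------------------------------------------------------------------------
# full multistage fit

def test_m_max_below_three_rejected():
    fm = _fm(30, 3)
    y = np.array([1] * 5 + [0] * 25)
    with pytest.raises(ValueError, match="at least 3"):
        MultistageTriage(fm, y, m_max=2)


def test_fit_reproducible_and_stage_immutable(small_cohort):
    cfg, (fm, labels) = small_cohort
    y = labels["A"]
    spec = BaseLearnerSpec("easy_ensemble", hyperparams={"n_estimators": 5})
    res1, trace1 = fit_multistage(spec, fm, y, k=5, seed=0, m_max=3)
    res2, trace2 = fit_multistage(spec, fm, y, k=5, seed=0, m_max=3)
    assert np.array_equal(trace1.p, trace2.p)
    assert np.array_equal(trace1.s, trace2.s)
    assert trace1.selected == trace2.selected
    for r1, r2 in zip(res1.stage_results, res2.stage_results):
        assert np.array_equal(r1.oof.probs, r2.oof.probs)
    # training an extra stage never alters earlier stage records
    res4, trace4 = fit_multistage(spec, fm, y, k=5, seed=0, m_max=4)
    assert np.allclose(trace4.p[:3], trace1.p)
    for r1, r4 in zip(res1.stage_results, res4.stage_results):
        assert np.array_equal(r1.oof.probs, r4.oof.probs)


def test_selected_stage_bounds_and_truncation(small_cohort):
    cfg, (fm, labels) = small_cohort
    res, trace = fit_multistage(
        BaseLearnerSpec("balanced_bagging", hyperparams={"n_estimators": 5}),
        fm,
        labels["B"],
        k=5,
        seed=1,
        m_max=4,
    )
    assert 2 <= res.selected_stage <= 3
    assert len(res.stages) == res.selected_stage
    # schema of stage j has n + (j-1) columns in cumulative mode
    for j, schema in enumerate(res.schemas, start=1):
        assert len(schema) == fm.n_features + (j - 1)


def test_all_equal_trajectory_selects_stage_two():
    from paintriage.elbow import StageTrace

    trace = StageTrace.from_trajectory([0.7, 0.7, 0.7, 0.7])
    assert trace.selected == 2


# ---------------------------------------------------------------------------
# inference chain

def test_single_stage_predict_equals_base_learner():
    rng = np.random.default_rng(9)
    y = np.array([1] * 8 + [0] * 32)
    fm = _fm(40, 5, seed=9)
    model = MultistageTriage(
        fm, y, base_spec=BaseLearnerSpec("balanced_random_forest",
                                         hyperparams={"n_estimators": 10}),
        k=4, m_max=3,
    )
    res = model.fit(seed=0)
    # force a single-stage chain to isolate the degenerate case
    res.selected_stage = 1
    res.stages = res.stages[:1]
    res.schemas = res.schemas[:1]
    pred = res.predict(fm)
    direct = res.stage_results[0].fitted_learner.predict_proba(fm.values)[:, 1]
    assert np.array_equal(pred.probs, direct)
    assert pred.provenance == "full_model"


def test_two_stage_chain_traced_by_hand():
    """The chain equals manually feeding stage-1 full-model output to stage 2."""
    y = np.array([1] * 6 + [0] * 24)
    fm = _fm(30, 4, seed=4)
    res, _ = fit_multistage(
        BaseLearnerSpec("balanced_bagging", hyperparams={"n_estimators": 5}),
        fm, y, k=3, seed=2, m_max=3,
    )
    if res.selected_stage < 2:  # pragma: no cover - selection is data-driven
        pytest.skip("chain shorter than two stages")
    chain = res.stages
    p1 = chain[0].predict_proba(fm.values)[:, 1]
    X2 = np.hstack([fm.values, p1[:, None]])
    expected = chain[1].predict_proba(X2)[:, 1]
    if res.selected_stage == 2:
        assert np.array_equal(res.predict(fm).probs, expected)
    else:
        p2 = expected
        X3 = np.hstack([fm.values, p1[:, None], p2[:, None]])
        assert np.array_equal(
            res.predict(fm).probs, chain[2].predict_proba(X3)[:, 1]
        )


def test_predict_range_and_schema_errors(small_cohort):
    cfg, (fm, labels) = small_cohort
    res, _ = fit_multistage(
        BaseLearnerSpec("easy_ensemble", hyperparams={"n_estimators": 3}),
        fm, labels["A"], k=5, seed=0, m_max=3,
    )
    pred = res.predict(fm)
    assert len(pred) == fm.n_patients
    assert np.all((pred.probs >= 0) & (pred.probs <= 1))
    df = fm.to_frame().drop(columns=[fm.feature_names[0]])
    with pytest.raises(SchemaError, match=fm.feature_names[0]):
        res.predict(df)


def test_save_load_roundtrip(small_cohort, tmp_path):
    cfg, (fm, labels) = small_cohort
    res, _ = fit_multistage(
        BaseLearnerSpec("easy_ensemble", hyperparams={"n_estimators": 3}),
        fm, labels["A"], k=5, seed=0, m_max=3,
    )
    res.save(tmp_path / "m")
    chain = LoadedChain.load(tmp_path / "m")
    assert chain.selected_stage == res.selected_stage
    assert np.allclose(chain.predict(fm.to_frame()).probs, res.predict(fm).probs)
    assert (tmp_path / "m" / "stage_trace.csv").exists()
    assert (tmp_path / "m" / "oof_probabilities.csv").exists()


def test_feature_importance_names_features(small_cohort):
    cfg, (fm, labels) = small_cohort
    res, _ = fit_multistage(
        BaseLearnerSpec("easy_ensemble", hyperparams={"n_estimators": 3}),
        fm, labels["A"], k=5, seed=0, m_max=3,
    )
    imp = res.feature_importance(top_k=5)
    assert len(imp) == 5
    assert set(imp["feature"]).issubset(set(res.schemas[-1]))
    assert (imp["importance"].to_numpy() >= 0).all()
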
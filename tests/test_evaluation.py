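"""CI convention, F1 reconciliation, stage accounting, calibration."""

import numpy as np
import pytest

from paintriage.evaluation import (
    DegenerateMetricsError,
    calibration_bins,
    final_metrics,
    probability_histogram,
    stage_accounting,
    summarize_fold_aucs,
    t_interval,
)


# ---------------------------------------------------------------------------
# t interval

def test_t_interval_reproduces_fold_convention():
    lo, hi = t_interval(0.8944, 0.0290, 10)
    assert round(lo, 4) == 0.8737
    assert round(hi, 4) == 0.9151


def test_t_interval_zero_sd_degenerates_to_point():
    assert t_interval(0.7, 0.0, 10) == (0.7, 0.7)


def test_t_interval_closed_form_k10():
    lo, hi = t_interval(0.5, 0.1, 10)
    t_quantile = 2.262157  # t_{0.975, 9}
    half = t_quantile * 0.1 / np.sqrt(10)
    assert lo == pytest.approx(0.5 - half, abs=1e-6)
    assert hi == pytest.approx(0.5 + half, abs=1e-6)


def test_t_interval_symmetry_and_errors():
    lo, hi = t_interval(0.83, 0.04, 7)
    assert hi - 0.83 == pytest.approx(0.83 - lo, abs=1e-15)
    with pytest.raises(ValueError):
        t_interval(0.5, 0.1, 1)
    with pytest.raises(ValueError):
        t_interval(0.5, -0.1, 10)


def test_summarize_fold_aucs_uses_sample_sd():
    aucs = [0.8, 0.9, 0.85, 0.95]
    s = summarize_fold_aucs(aucs)
    assert s.mean == pytest.approx(np.mean(aucs))
    assert s.sd == pytest.approx(np.std(aucs, ddof=1))
    assert s.ci_low <= s.mean <= s.ci_high


# ---------------------------------------------------------------------------
# final metrics / F1

def test_f1_reconciles_precision_recall():
    def f1(p, r):
        return 2 * p * r / (p + r)

    assert round(f1(0.16, 0.97), 2) == 0.27
    assert round(f1(0.13, 0.87), 2) == 0.23


def test_final_metrics_confusion_and_f1(small_cohort):
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0])
    probs = np.array([0.9, 0.8, 0.2, 0.7, 0.3, 0.1, 0.2, 0.6])
    m, ci = final_metrics(probs, y, threshold=0.5, fold_aucs=[0.8, 0.9])
    # tp=2 fn=1 fp=2 tn=3
    assert m.precision == pytest.approx(0.5)
    assert m.recall == pytest.approx(2 / 3)
    assert m.f1 == pytest.approx(2 * 0.5 * (2 / 3) / (0.5 + 2 / 3))
    assert ci is not None and ci.k == 2


def test_final_metrics_zero_denominator_f1():
    y = np.array([1, 1, 0, 0])
    probs = np.array([0.1, 0.2, 0.3, 0.4])  # nothing called positive
    m, _ = final_metrics(probs, y, threshold=0.5)
    assert m.precision == 0.0 and m.f1 == 0.0
    assert m.degenerate == "no_predicted_positives"


def test_final_metrics_no_positives_raises():
    with pytest.raises(DegenerateMetricsError):
        final_metrics(np.array([0.1, 0.9]), np.array([0, 0]))


# ---------------------------------------------------------------------------
# stage accounting

def _narrative_instance(n, n_pos, stage1_correct_pos, newly_pos, stage_count=2):
    """Build per-stage probability vectors realising a capture narrative."""
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    p1 = np.full(n, 0.1)
    p1[:stage1_correct_pos] = 0.9
    p2 = p1.copy()
    p2[stage1_correct_pos : stage1_correct_pos + newly_pos] = 0.9
    return y, [p1, p2][:stage_count]


def test_accounting_scs_like_narrative():
    """126 positives: 77 captured at stage 1, 33 of the remaining 49 newly
    captured at stage 2, none lost → 110 final true positives."""
    y, stages = _narrative_instance(3552, 126, 77, 33)
    acc = stage_accounting(stages, y, threshold=0.5)
    assert acc.positive.captured_stage1 == 77
    assert acc.positive.newly_captured[2] == 33
    assert acc.positive.lost[2] == 0
    assert acc.positive.final_correct == 110
    assert acc.tpr_final == pytest.approx(110 / 126)


def test_accounting_single_stage_degenerates_to_confusion():
    y = np.array([1, 1, 1, 0, 0])
    probs = np.array([0.9, 0.2, 0.8, 0.1, 0.9])
    acc = stage_accounting([probs], y, threshold=0.5)
    assert acc.positive.captured_stage1 == 2
    assert acc.positive.newly_captured == {}
    assert acc.negative.captured_stage1 == 1
    assert acc.positive.final_correct == 2


def _brute_force_accounting(preds, y, cls):
    correct = (preds == y[:, None])[y == cls]
    n, m = correct.shape
    out = {
        "captured_stage1": sum(c[0] for c in correct),
        "never": sum(not any(c) for c in correct),
        "final": sum(c[-1] for c in correct),
        "newly": {},
        "lost": {},
    }
    for j in range(1, m):
        out["newly"][j + 1] = sum(
            (not any(c[:j])) and c[j] for c in correct
        )
        out["lost"][j + 1] = sum(any(c[:j]) and not c[j] for c in correct)
    return out


@pytest.mark.parametrize("seed", range(10))
def test_accounting_matches_per_patient_enumeration(seed):
    rng = np.random.default_rng(seed)
    n, m = 200, int(rng.integers(2, 5))
    y = rng.integers(0, 2, n)
    stages = [rng.random(n) for _ in range(m)]
    acc = stage_accounting(stages, y, threshold=0.5)
    preds = np.column_stack([s > 0.5 for s in stages])
    for cls, side in ((1, acc.positive), (0, acc.negative)):
        oracle = _brute_force_accounting(preds, y, cls)
        assert side.captured_stage1 == oracle["captured_stage1"]
        assert side.never_captured == oracle["never"]
        assert side.final_correct == oracle["final"]
        assert side.newly_captured == oracle["newly"]
        assert side.lost == oracle["lost"]
        # reconciliation: totals partition the class
        assert side.total == int(np.sum(y == cls))


def test_accounting_reconciliation_invariant():
    """captured_stage1 + net per-stage changes equals final-stage correct."""
    rng = np.random.default_rng(123)
    for _ in range(20):
        n = int(rng.integers(20, 120))
        m = int(rng.integers(2, 5))
        y = rng.integers(0, 2, n)
        stages = [rng.random(n) for _ in range(m)]
        acc = stage_accounting(stages, y, threshold=0.5)
        for side in (acc.positive, acc.negative):
            net = side.captured_stage1
            by_stage = side.correct_by_stage
            assert by_stage[0] == side.captured_stage1
            for j in range(1, m):
                net += by_stage[j] - by_stage[j - 1]
            assert net == side.final_correct
            assert all(v >= 0 for v in side.newly_captured.values())
            assert all(v >= 0 for v in side.lost.values())


# ---------------------------------------------------------------------------
# calibration

def test_calibration_single_occupied_bin():
    probs = np.full(30, 0.05)
    tab = calibration_bins(probs, np.zeros(30, dtype=int), n_bins=10)
    df = tab.table
    assert df["count"].sum() == 30
    occupied = df[~df["empty"]]
    assert len(occupied) == 1
    assert occupied["observed_fraction"].iloc[0] == 0.0


def test_calibration_weighted_mean_equals_prevalence():
    rng = np.random.default_rng(5)
    probs = rng.random(500)
    y = rng.integers(0, 2, 500)
    tab = calibration_bins(probs, y, n_bins=7)
    df = tab.table[~tab.table["empty"]]
    weighted = np.sum(df["count"] * df["observed_fraction"]) / df["count"].sum()
    assert weighted == pytest.approx(y.mean())
    assert tab.prevalence == pytest.approx(y.mean())


def test_calibration_of_perfectly_calibrated_draw():
    rng = np.random.default_rng(11)
    probs = rng.random(10_000)
    y = (rng.random(10_000) < probs).astype(int)
    df = calibration_bins(probs, y, n_bins=10).table
    occ = df[~df["empty"]]
    gap = np.abs(occ["observed_fraction"] - occ["mean_predicted"])
    assert gap.max() < 0.05


def test_calibration_edges_and_errors():
    with pytest.raises(ValueError):
        calibration_bins([0.5], [1], n_bins=0)
    with pytest.raises(ValueError):
        calibration_bins([1.2], [1], n_bins=5)
    df = calibration_bins([0.0, 1.0], [0, 1], n_bins=4).table
    assert df["count"].sum() == 2
    assert df.iloc[-1]["count"] == 1  # prob 1.0 falls in the closed last bin


# ---------------------------------------------------------------------------
# probability histogram

def test_histogram_conservation(small_cohort):
    rng = np.random.default_rng(3)
    n = 120
    y = rng.integers(0, 2, n)
    stages = [rng.random(n), rng.random(n)]
    df = probability_histogram(stages, y, bin_width=0.1)
    for stage in (1, 2):
        sub = df[df["stage"] == stage]
        assert sub["count_all"].sum() == n
        assert sub["count_positive"].sum() == int(y.sum())


def test_histogram_degenerate_cases():
    y = np.zeros(15, dtype=int)
    df = probability_histogram([np.full(15, 0.4)], y, bin_width=0.1)
    assert df["count_all"].max() == 15
    assert float(df.loc[df["count_all"] == 15, "bin_lo"].iloc[0]) == pytest.approx(0.4)
    same = np.linspace(0, 1, 15)
    df2 = probability_histogram([same, same], y)
    a = df2[df2["stage"] == 1]["count_all"].to_numpy()
    b = df2[df2["stage"] == 2]["count_all"].to_numpy()
    assert np.array_equal(a, b)
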
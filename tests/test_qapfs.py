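"""Quality-adjusted survival engine: KM restricted mean, per-patient
adjustment, bootstrap inference."""

import numpy as np
import pandas as pd
import pytest

from qapro import ConfigurationError, InsufficientDataError
from qapro.qapfs import (
    bootstrap_difference,
    group_qapfs,
    km_restricted_mean,
    patient_qapfs,
    patient_quality_metrics,
    unadjusted_pfs,
)


def qa_frame(times, events, arms, pids=None):
    return pd.DataFrame({
        "patient_id": pids or [f"p{i}" for i in range(len(times))],
        "arm": arms, "qa_months": times, "event": events,
    })


def test_km_mean_equals_arithmetic_mean_without_censoring():
    rng = np.random.default_rng(5)
    for _ in range(50):
        times = rng.uniform(0.5, 30, int(rng.integers(2, 40)))
        mean, _ = km_restricted_mean(times, np.ones(times.size, bool))
        assert mean == pytest.approx(times.mean(), abs=1e-9)


def test_km_hand_computed_censored_example():
    """times 10, 20+ (censored), 30: S=1 on [0,10), 2/3 on [10,30), 0 after;
    area = 10 + 20*(2/3) = 23.333..."""
    mean, se = km_restricted_mean([10, 20, 30], [True, False, True])
    assert mean == pytest.approx(10 + 20 * 2 / 3, abs=1e-9)
    assert se > 0


def test_km_matches_lifelines_on_censored_data():
    """Independent cross-check of the KM curve-area against lifelines."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    rng = np.random.default_rng(17)
    for _ in range(10):
        n = int(rng.integers(10, 60))
        times = rng.exponential(15, n)
        events = rng.random(n) < 0.7
        if not events.any():
            continue
        mean, _ = km_restricted_mean(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        expected = restricted_mean_survival_time(kmf, t=times.max())
        assert mean == pytest.approx(expected, rel=1e-9)


def test_km_all_censored_errors():
    with pytest.raises(InsufficientDataError):
        km_restricted_mean([5, 10], [False, False])


def test_patient_qapfs_arithmetic_and_exclusions():
    sv = pd.DataFrame({"patient_id": ["p1", "p2", "p3"], "arm": ["A", "A", "B"],
                       "pfs_months": [20.0, 12.0, 8.0], "event": [True, False, True]})
    metrics = pd.DataFrame({"patient_id": ["p1", "p2"], "metric_value": [0.80, 1.0],
                            "n_assessments": [5, 3]})
    qa, excluded = patient_qapfs(sv, metrics)
    assert qa.set_index("patient_id")["qa_months"].to_dict() == {"p1": 16.0, "p2": 12.0}
    assert qa.set_index("patient_id")["event"].to_dict() == {"p1": True, "p2": False}
    assert excluded == [{"patient_id": "p3", "reason": "no scored assessment"}]


def test_negative_utility_propagates_with_warning():
    sv = pd.DataFrame({"patient_id": ["p1", "p2"], "arm": ["A", "A"],
                       "pfs_months": [10.0, 10.0], "event": [True, True]})
    metrics = pd.DataFrame({"patient_id": ["p1", "p2"], "metric_value": [-0.05, 0.5],
                            "n_assessments": [2, 2]})
    with pytest.warns(UserWarning, match="negative"):
        qa, _ = patient_qapfs(sv, metrics)
    assert qa["qa_months"].min() == pytest.approx(-0.5)
    qa_floored, _ = patient_qapfs(sv, metrics, floor_at_zero=True)
    assert qa_floored["qa_months"].min() == 0.0


def test_group_qapfs_single_patient_errors():
    qa = qa_frame([10.0, 12.0, 14.0], [True, True, True], ["A", "A", "B"])
    with pytest.raises(InsufficientDataError):
        group_qapfs(qa)


def test_unadjusted_pfs_is_identity_metric():
    rng = np.random.default_rng(23)
    times = rng.uniform(1, 30, 40)
    events = rng.random(40) < 0.8
    arms = ["A"] * 20 + ["B"] * 20
    sv = pd.DataFrame({"patient_id": [f"p{i}" for i in range(40)], "arm": arms,
                       "pfs_months": times, "event": events})
    metrics = pd.DataFrame({"patient_id": [f"p{i}" for i in range(40)],
                            "metric_value": 1.0, "n_assessments": 1})
    qa, _ = patient_qapfs(sv, metrics)
    pd.testing.assert_frame_equal(group_qapfs(qa), unadjusted_pfs(sv))


def test_unadjusted_pfs_empty_errors():
    with pytest.raises(InsufficientDataError):
        unadjusted_pfs(pd.DataFrame(columns=["patient_id", "arm", "pfs_months", "event"]))


def test_qapfs_never_exceeds_unadjusted_pfs_on_fuzz_trials():
    rng = np.random.default_rng(31)
    for _ in range(20):
        n = 30
        sv = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(2 * n)],
            "arm": ["A"] * n + ["B"] * n,
            "pfs_months": rng.uniform(1, 30, 2 * n),
            "event": rng.random(2 * n) < 0.8,
        })
        if not sv.groupby("arm")["event"].any().all():
            continue
        metrics = pd.DataFrame({"patient_id": sv["patient_id"],
                                "metric_value": rng.uniform(0, 1, 2 * n),
                                "n_assessments": 1})
        qa, _ = patient_qapfs(sv, metrics)
        adj = group_qapfs(qa).set_index("arm")["mean_months"]
        raw = unadjusted_pfs(sv).set_index("arm")["mean_months"]
        assert (adj <= raw + 1e-9).all()


def test_quality_metric_averages_available_assessments():
    scores = pd.DataFrame({
        "patient_id": ["p1"] * 3 + ["p2"],
        "visit_month": [0, 2, 4, 0],
        "domain_id": "summary",
        "score": [80.0, 90.0, np.nan, 60.0],
        "n_items_answered": 13,
    })
    m = patient_quality_metrics(scores, "summary").set_index("patient_id")
    assert m.loc["p1", "metric_value"] == pytest.approx(0.85)  # NaN visit ignored
    assert m.loc["p1", "n_assessments"] == 2
    assert m.loc["p2", "metric_value"] == pytest.approx(0.60)


def test_bootstrap_difference_null_and_config():
    rng = np.random.default_rng(41)
    times = rng.uniform(5, 25, 60)
    qa = qa_frame(np.concatenate([times, times]), [True] * 120, ["A"] * 60 + ["B"] * 60)
    with pytest.raises(ConfigurationError):
        bootstrap_difference(qa, "A", "B", n_boot=10, seed=1)
    res = bootstrap_difference(qa, "A", "B", n_boot=1000, seed=1)
    assert res["difference"] == pytest.approx(0.0, abs=1e-12)  # identical arms
    assert res["ci_low"] <= 0.0 <= res["ci_high"]
    assert res["p_value"] > 0.5


def test_bootstrap_detects_known_shift():
    rng = np.random.default_rng(43)
    base = rng.uniform(5, 25, 200)
    qa = qa_frame(np.concatenate([base + 3.0, base]), [True] * 400,
                  ["A"] * 200 + ["B"] * 200)
    res = bootstrap_difference(qa, "A", "B", n_boot=1000, seed=2)
    assert res["difference"] == pytest.approx(3.0, abs=1e-9)
    assert res["ci_low"] > 0.0
    assert res["p_value"] <= 0.01


def test_pipeline_monotonicity_in_quality(small_scores, small_trial):
    """Uniformly raising every summary score strictly raises both arms'
    QAPFS."""
    sv = small_trial.survival
    better = small_scores.copy()
    mask = (better["domain_id"] == "summary") & better["score"].notna()
    better.loc[mask, "score"] = np.minimum(better.loc[mask, "score"] + 10, 100.0)
    qa_lo, _ = patient_qapfs(sv, patient_quality_metrics(small_scores, "summary"))
    qa_hi, _ = patient_qapfs(sv, patient_quality_metrics(better, "summary"))
    lo = group_qapfs(qa_lo).set_index("arm")["mean_months"]
    hi = group_qapfs(qa_hi).set_index("arm")["mean_months"]
    assert (hi > lo).all()
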
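"""Responder classification, odds ratios, time to improvement, symptom flags."""

import numpy as np
import pandas as pd
import pytest

from qapro import InsufficientDataError
from qapro.responder import (
    IMPROVED,
    STABLE,
    UNCLASSIFIABLE,
    WORSENED,
    classify_change,
    classify_changes,
    kd_symptom_analysis,
    responder_table,
    time_to_first_improvement,
)
from qapro.scoring import raw_item_to_0_100


def scores_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "visit_month", "domain_id", "score"])


@pytest.mark.parametrize(
    "baseline,followup,threshold,sign,expected",
    [
        (50, 75, 20, 1, IMPROVED),     # +25 on a functional domain
        (50, 65, 20, 1, STABLE),       # +15 < 20
        (40, 75, 33, 1, IMPROVED),     # body image, +35 >= 33
        (50, 25, 20, 1, WORSENED),
        (50, 20, 20, -1, IMPROVED),    # symptom falling by 30
        (np.nan, 60, 20, 1, UNCLASSIFIABLE),
        (60, np.nan, 20, 1, UNCLASSIFIABLE),
    ],
)
def test_classify_change(baseline, followup, threshold, sign, expected):
    assert classify_change(baseline, followup, threshold, sign) == expected


def test_classify_change_antisymmetric():
    rng = np.random.default_rng(11)
    for _ in range(200):
        a, b = rng.uniform(0, 100, 2)
        fwd = classify_change(a, b, 20, 1)
        rev = classify_change(b, a, 20, 1)
        swap = {IMPROVED: WORSENED, WORSENED: IMPROVED, STABLE: STABLE}
        assert rev == swap[fwd]


def test_partition_covers_all_patients(small_scores, small_trial):
    cls = classify_changes(small_scores, domains=["physical"])
    n_patients_with_rows = small_scores.loc[
        small_scores["domain_id"] == "physical", "patient_id"
    ].nunique()
    per_visit = cls.groupby("visit_month")["category"].count()
    assert (per_visit == n_patients_with_rows).all()
    assert set(cls["category"]) <= {IMPROVED, STABLE, WORSENED, UNCLASSIFIABLE}


def arm_frame(n_a, n_b):
    return pd.DataFrame({
        "patient_id": [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)],
        "arm": ["A"] * n_a + ["B"] * n_b,
    })


def classification_frame(counts):
    """counts: {arm: {category: n}} -> classification rows at one visit."""
    rows = []
    for arm, cats in counts.items():
        i = 0
        for cat, n in cats.items():
            for _ in range(n):
                rows.append({"patient_id": f"{arm.lower()}{i}", "domain_id": "physical",
                             "visit_month": 4, "category": cat})
                i += 1
    return pd.DataFrame(rows)


def test_responder_table_identical_arms_is_null():
    cls = classification_frame({"A": {IMPROVED: 10, STABLE: 90}, "B": {IMPROVED: 10, STABLE: 90}})
    tab = responder_table(cls, arm_frame(100, 100), category=IMPROVED)
    assert tab["odds_ratio"].iloc[0] == pytest.approx(1.0)
    assert tab["p_value"].iloc[0] == pytest.approx(1.0)


def test_responder_table_hand_computed_odds_ratio():
    """(10 improved, 90 other) vs (5, 95): OR = 10*95 / (90*5) = 2.111."""
    cls = classification_frame({"A": {IMPROVED: 10, STABLE: 90}, "B": {IMPROVED: 5, STABLE: 95}})
    tab = responder_table(cls, arm_frame(100, 100), category=IMPROVED)
    assert tab["odds_ratio"].iloc[0] == pytest.approx(950 / 450, rel=1e-9)
    assert not tab["zero_cell_corrected"].iloc[0]


def test_responder_table_zero_cell_correction_flagged():
    cls = classification_frame({"A": {IMPROVED: 0, STABLE: 50}, "B": {IMPROVED: 5, STABLE: 45}})
    tab = responder_table(cls, arm_frame(50, 50), category=IMPROVED)
    assert tab["zero_cell_corrected"].iloc[0]
    assert np.isfinite(tab["odds_ratio"].iloc[0])


def test_responder_table_empty_arm_errors():
    cls = classification_frame({"A": {IMPROVED: 10, STABLE: 40}, "B": {UNCLASSIFIABLE: 50}})
    with pytest.raises(InsufficientDataError):
        responder_table(cls, arm_frame(50, 50), category=IMPROVED)


def test_responder_proportions_recover_generating_probability():
    """With a known improvement probability per arm the observed
    proportions converge (binomial tolerance at n=500)."""
    rng = np.random.default_rng(99)
    n, p_a, p_b = 500, 0.30, 0.15
    counts = {
        "A": {IMPROVED: int(rng.binomial(n, p_a))},
        "B": {IMPROVED: int(rng.binomial(n, p_b))},
    }
    counts["A"][STABLE] = n - counts["A"][IMPROVED]
    counts["B"][STABLE] = n - counts["B"][IMPROVED]
    cls = classification_frame(counts)
    tab = responder_table(cls, arm_frame(n, n), category=IMPROVED)
    for arm, p in (("A", p_a), ("B", p_b)):
        tol = 4 * np.sqrt(p * (1 - p) / n)
        assert abs(tab[f"prop_improved_{arm}"].iloc[0] - p) < tol


def survival_frame(pids, arms, country=None):
    df = pd.DataFrame({"patient_id": pids, "arm": arms})
    if country is not None:
        df["country"] = country
    return df


def test_time_to_first_improvement_event_and_censoring():
    rows = []
    # improves at month 4 (72 - 50 = 22 >= 20)
    for m, s in zip([0, 2, 4, 6], [50, 55, 72, 80]):
        rows.append(("p1", m, "physical", s))
    # never improves -> censored at end of study
    for m, s in zip([0, 2, 4, 6], [50, 55, 60, 65]):
        rows.append(("p2", m, "physical", s))
    # baseline 85 -> excluded (no room for improvement)
    for m, s in zip([0, 2, 4], [85, 90, 95]):
        rows.append(("p3", m, "physical", s))
    # more patients so the Cox fit has two arms
    for m, s in zip([0, 2, 4, 6], [40, 45, 70, 75]):
        rows.append(("p4", m, "physical", s))
    sv = survival_frame(["p1", "p2", "p3", "p4"], ["A", "A", "B", "B"])
    times, cox = time_to_first_improvement(scores_frame(rows), sv, ["physical"],
                                           end_of_study=22)
    t = times.set_index("patient_id")
    assert t.loc["p1", "time_months"] == 4 and t.loc["p1", "event"]
    assert t.loc["p2", "time_months"] == 22 and not t.loc["p2", "event"]
    assert "p3" not in t.index
    assert cox["n_included"].iloc[0] == 3


def test_body_image_ceiling_uses_thirty_three_point_room():
    rows = [("p1", 0, "body_image", 70.0), ("p1", 2, "body_image", 100.0),
            ("p2", 0, "body_image", 60.0), ("p2", 2, "body_image", 100.0)]
    sv = survival_frame(["p1", "p2"], ["A", "B"])
    times, _ = time_to_first_improvement(scores_frame(rows), sv, ["body_image"],
                                         end_of_study=22)
    # baseline 70 > 100 - 33 = 67 -> excluded; baseline 60 improves by 40
    assert list(times["patient_id"]) == ["p2"]
    assert times["event"].iloc[0]


def test_cox_recovers_known_rate_ratio():
    """Exponential improvement times with hazard ratio 1.5: the Cox CI
    covers the truth in >= 90% of 200 replicates."""
    true_hr = 1.5
    n = 50
    covered = 0
    n_reps = 200
    for rep in range(n_reps):
        rng = np.random.default_rng(3000 + rep)
        rows, pids, arms = [], [], []
        for arm, rate in (("A", 0.12 * true_hr), ("B", 0.12)):
            t = rng.exponential(1.0 / rate, n)
            base = rng.uniform(35, 65, n)  # improvement-independent baselines
            for i in range(n):
                pid = f"{arm}{i}"
                pids.append(pid)
                arms.append(arm)
                rows.append((pid, 0, "physical", base[i]))
                if t[i] <= 22:  # improvement observed at its exact time
                    rows.append((pid, float(t[i]), "physical", base[i] + 25.0))
        times, cox = time_to_first_improvement(
            scores_frame(rows), survival_frame(pids, arms), ["physical"], end_of_study=22)
        if cox["ci_low"].iloc[0] <= true_hr <= cox["ci_high"].iloc[0]:
            covered += 1
    assert covered / n_reps >= 0.90


def test_kd_symptom_flags_and_cumulative_incidence():
    assert raw_item_to_0_100(2) == 33   # any-symptom cutoff
    assert raw_item_to_0_100(3) == 67   # also moderate/severe (>= 66)
    rows = []
    # p1: insomnia develops (q11: 1 at baseline, 3 at month 2)
    # p2: never (q11 stays 1); p3: already symptomatic at baseline
    for pid, seq in (("p1", [1, 3]), ("p2", [1, 1]), ("p3", [2, 4])):
        for m, r in zip([0, 2], seq):
            rows.append({"patient_id": pid, "visit_month": m, "instrument": "QLQC30",
                         "item_id": "q11", "response": r})
    arms = survival_frame(["p1", "p2", "p3"], ["A", "A", "B"])
    out = kd_symptom_analysis(pd.DataFrame(rows), arms)
    any_row = out[(out["symptom"] == "insomnia") & (out["severity"] == "any")].iloc[0]
    # p3 (arm B) is above the cutoff at baseline: not at risk
    assert any_row["n_at_risk_A"] == 2 and any_row["developed_A"] == 1
    assert any_row["n_at_risk_B"] == 0
    mod = out[(out["symptom"] == "insomnia") & (out["severity"] == "moderate_severe")].iloc[0]
    assert mod["n_at_risk_B"] == 1  # 33 < 66: p3 at risk for moderate/severe
    assert mod["developed_B"] == 1  # reaches 100 at month 2
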
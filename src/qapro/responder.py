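"""Patient-level threshold ("responder") analyses.

Three analyses, all driven by minimal-important-difference-scale
thresholds on 0-100 domain scores:

* improved / stable / worsened classification of change from baseline
  (default threshold 20 points for multi-item domains, 33 for the
  single-item body-image domain), with per-visit arm contrasts as odds
  ratios (Woolf CI) and chi-square tests;
* time to first recorded improvement, censored at end of study, excluding
  patients whose baseline leaves no arithmetic room for a full-threshold
  improvement, compared between arms with a Cox model adjusted for
  baseline score and country;
* treatment-related symptom dichotomization of raw item scores at >= 33
  ("any") and >= 66 ("moderate to severe") points, with cumulative
  "developed during the study period" proportions among patients below
  threshold at baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InsufficientDataError
from .scoring import load_instrument_spec, raw_item_to_0_100

__all__ = [
    "classify_change",
    "classify_changes",
    "responder_table",
    "time_to_first_improvement",
    "kd_symptom_analysis",
    "default_threshold",
    "KD_SYMPTOM_ITEMS",
]

IMPROVED, STABLE, WORSENED, UNCLASSIFIABLE = "improved", "stable", "worsened", "unclassifiable"

#: Treatment-related symptoms and their constituent items (configurable;
#: the last entry is the myeloma-module restlessness/agitation item).
KD_SYMPTOM_ITEMS = {
    "fatigue": ["q10", "q12", "q18"],
    "nausea_vomiting": ["q14", "q15"],
    "dyspnea": ["q8"],
    "insomnia": ["q11"],
    "diarrhea": ["q17"],
    "agitation_irritation": ["my13"],
}

ANY_CUTOFF = 33.0
MODERATE_CUTOFF = 66.0


def default_threshold(domain_id: str) -> float:
    """Responder threshold: 33 points for single-item body image, 20 otherwise."""
    return 33.0 if domain_id == "body_image" else 20.0


def _improvement_sign(domain_id: str, spec: pd.DataFrame) -> int:
    row = spec.loc[spec["domain_id"] == domain_id, "direction"]
    if row.empty:
        raise KeyError(f"unknown domain {domain_id!r}")
    return -1 if row.iloc[0] == "symptom" else 1


def classify_change(baseline, followup, threshold: float = 20.0, improvement_sign: int = 1) -> str:
    """Classify a change from baseline against a responder threshold.

    ``improvement_sign`` is +1 when higher scores are better (functional
    domains, global health) and -1 for symptom domains.  Either score
    missing makes the change unclassifiable.
    """
    if baseline is None or followup is None or np.isnan(baseline) or np.isnan(followup):
        return UNCLASSIFIABLE
    delta = (followup - baseline) * improvement_sign
    if delta >= threshold:
        return IMPROVED
    if delta <= -threshold:
        return WORSENED
    return STABLE


def classify_changes(domain_scores: pd.DataFrame, domains=None, thresholds=None,
                     baseline_month: int = 0, spec: pd.DataFrame | None = None) -> pd.DataFrame:
    """Classify every patient x domain x post-baseline visit.

    Emits one row per randomized patient per domain per visit present in
    the score table, so improved + stable + worsened + unclassifiable
    partitions the patients with a score row at that visit.
    """
    if spec is None:
        spec = load_instrument_spec()
    scores = domain_scores
    if domains is not None:
        scores = scores[scores["domain_id"].isin(domains)]
    wide = scores.pivot_table(index=["patient_id", "domain_id"], columns="visit_month",
                              values="score", dropna=False)
    rows = []
    for (pid, dom), series in wide.iterrows():
        base = series.get(baseline_month, np.nan)
        thr = (thresholds or {}).get(dom, default_threshold(dom))
        sign = _improvement_sign(dom, spec)
        for visit in series.index:
            if visit == baseline_month:
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "domain_id": dom,
                    "visit_month": visit,
                    "category": classify_change(base, series[visit], thr, sign),
                }
            )
    return pd.DataFrame(rows)


def _odds_ratio_2x2(a, b, c, d):
    """Odds ratio (a*d)/(b*c) with Woolf 95% CI; Haldane-Anscombe 0.5
    correction when any cell is zero (flagged)."""
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    return or_, or_ * np.exp(-z * se), or_ * np.exp(z * se), corrected


def _chi2_p(table: np.ndarray) -> float:
    """Chi-square test of homogeneity without continuity correction."""
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan
    return float(stats.chi2_contingency(table, correction=False)[1])


def responder_table(classifications: pd.DataFrame, arms: pd.DataFrame,
                    category: str = IMPROVED) -> pd.DataFrame:
    """Per-domain, per-visit arm comparison of responder proportions.

    ``arms`` maps ``patient_id`` to ``arm`` (exactly two arms).  The
    contrasted ``category`` is compared against all other classifiable
    categories: 2x2 odds ratio with Woolf CI and a chi-square test of
    homogeneity.  Proportions for all three categories are emitted, with
    classifiable patients as the denominator.
    """
    arm_levels = list(pd.unique(arms["arm"]))
    if len(arm_levels) != 2:
        raise InsufficientDataError(f"need exactly 2 arms, got {arm_levels}")
    merged = classifications.merge(arms[["patient_id", "arm"]], on="patient_id")
    rows = []
    for (dom, visit), grp in merged.groupby(["domain_id", "visit_month"]):
        cls = grp[grp["category"] != UNCLASSIFIABLE]
        counts = {
            arm: cls[cls["arm"] == arm]["category"].value_counts()
            for arm in arm_levels
        }
        n = {arm: int(counts[arm].sum()) for arm in arm_levels}
        if min(n.values()) == 0:
            raise InsufficientDataError(
                f"{dom} at month {visit}: an arm has no classifiable patients"
            )
        a = counts[arm_levels[0]].get(category, 0)
        c = counts[arm_levels[1]].get(category, 0)
        or_, lo, hi, flagged = _odds_ratio_2x2(a, n[arm_levels[0]] - a, c, n[arm_levels[1]] - c)
        p = _chi2_p(np.array([[a, n[arm_levels[0]] - a], [c, n[arm_levels[1]] - c]]))
        row = {"domain_id": dom, "visit_month": visit, "category": category,
               "odds_ratio": or_, "ci_low": lo, "ci_high": hi, "p_value": p,
               "zero_cell_corrected": flagged}
        for arm in arm_levels:
            row[f"n_{arm}"] = n[arm]
            for cat in (IMPROVED, STABLE, WORSENED):
                row[f"prop_{cat}_{arm}"] = counts[arm].get(cat, 0) / n[arm]
        rows.append(row)
    return pd.DataFrame(rows)


def time_to_first_improvement(domain_scores: pd.DataFrame, survival: pd.DataFrame,
                              domains, end_of_study: float, thresholds=None,
                              ceiling: float = 80.0, baseline_month: int = 0,
                              spec: pd.DataFrame | None = None):
    """Time from randomization to first qualifying improvement, per domain.

    Exclusions: no baseline score, or a baseline leaving no arithmetic
    room for a full-threshold improvement (functional/global-health
    baseline above ``ceiling`` = 80 points; body image above
    ``100 - threshold``).  Patients never improving are censored at
    ``end_of_study``.  The arm contrast is a Cox proportional-hazards
    model with treatment, baseline score and country as covariates
    (country omitted when absent or constant).

    Returns ``(times, cox)``: the per-patient event table and a per-domain
    table of hazard ratios with 95% CIs.
    """
    from lifelines import CoxPHFitter

    if spec is None:
        spec = load_instrument_spec()
    arm_levels = list(pd.unique(survival["arm"]))
    time_rows, cox_rows = [], []
    for dom in domains:
        thr = (thresholds or {}).get(dom, default_threshold(dom))
        sign = _improvement_sign(dom, spec)
        dom_ceiling = 100.0 - thr if dom == "body_image" else ceiling
        sub = domain_scores[domain_scores["domain_id"] == dom]
        wide = sub.pivot_table(index="patient_id", columns="visit_month", values="score",
                               dropna=False)
        for pid, series in wide.iterrows():
            base = series.get(baseline_month, np.nan)
            if np.isnan(base):
                continue
            if sign > 0 and base > dom_ceiling:
                continue
            if sign < 0 and base < thr:
                continue
            event, t = False, end_of_study
            for visit in sorted(v for v in series.index if v > baseline_month):
                val = series[visit]
                if not np.isnan(val) and (val - base) * sign >= thr:
                    event, t = True, float(visit)
                    break
            time_rows.append({"patient_id": pid, "domain_id": dom, "time_months": t,
                              "event": event, "baseline": float(base)})
    times = pd.DataFrame(time_rows)
    if times.empty:
        raise InsufficientDataError("no patients eligible for time-to-improvement")

    merged = times.merge(survival[["patient_id", "arm"] +
                                  (["country"] if "country" in survival else [])],
                         on="patient_id")
    for dom, grp in merged.groupby("domain_id"):
        df = grp.copy()
        df["treatment"] = (df["arm"] == arm_levels[0]).astype(float)
        cols = ["time_months", "event", "treatment", "baseline"]
        if "country" in df and df["country"].nunique() > 1:
            dummies = pd.get_dummies(df["country"], prefix="country", drop_first=True, dtype=float)
            df = pd.concat([df, dummies], axis=1)
            cols += list(dummies.columns)
        cph = CoxPHFitter()
        try:
            cph.fit(df[cols], duration_col="time_months", event_col="event")
            hr = float(np.exp(cph.params_["treatment"]))
            lo, hi = np.exp(cph.confidence_intervals_.loc["treatment"]).tolist()
            p = float(cph.summary.loc["treatment", "p"])
        except Exception:  # non-convergence on degenerate strata
            hr = lo = hi = p = np.nan
        cox_rows.append({"domain_id": dom, "hazard_ratio": hr, "ci_low": lo,
                         "ci_high": hi, "p_value": p,
                         "n_included": len(grp), "n_improved": int(grp["event"].sum())})
    return times, pd.DataFrame(cox_rows)


def kd_symptom_analysis(items: pd.DataFrame, arms: pd.DataFrame,
                        symptom_items: dict | None = None, baseline_month: int = 0,
                        max_month: float | None = None) -> pd.DataFrame:
    """Proportions of patients developing treatment-related symptoms.

    Raw item responses are converted to the printed 0/33/67/100 scale.  A
    symptom is present at a visit when any constituent item scores at or
    above the cutoff (33 = any symptom, 66 = moderate to severe).  For
    each symptom and cutoff, patients below the cutoff at baseline form
    the denominator, and "developed during the study period" means
    reaching the cutoff at any post-baseline visit up to ``max_month``.
    Arms are compared with a chi-square test and a Woolf-CI odds ratio.
    """
    symptom_items = symptom_items or KD_SYMPTOM_ITEMS
    arm_levels = list(pd.unique(arms["arm"]))
    if len(arm_levels) != 2:
        raise InsufficientDataError(f"need exactly 2 arms, got {arm_levels}")
    all_items = sorted({i for ids in symptom_items.values() for i in ids})
    df = items[items["item_id"].isin(all_items)].copy()
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    df = df.dropna(subset=["response"])
    df["raw100"] = df["response"].map(lambda r: raw_item_to_0_100(int(r)))
    if max_month is not None:
        df = df[df["visit_month"] <= max_month]
    rows = []
    for symptom, item_ids in symptom_items.items():
        sub = df[df["item_id"].isin(item_ids)]
        worst = sub.groupby(["patient_id", "visit_month"])["raw100"].max().reset_index()
        for cutoff, label in ((ANY_CUTOFF, "any"), (MODERATE_CUTOFF, "moderate_severe")):
            base = worst[worst["visit_month"] == baseline_month]
            at_risk = set(base.loc[base["raw100"] < cutoff, "patient_id"])
            post = worst[(worst["visit_month"] > baseline_month)
                         & worst["patient_id"].isin(at_risk)]
            developed = set(post.loc[post["raw100"] >= cutoff, "patient_id"])
            counts = {}
            for arm in arm_levels:
                arm_pids = set(arms.loc[arms["arm"] == arm, "patient_id"])
                n_risk = len(at_risk & arm_pids)
                n_dev = len(developed & arm_pids)
                counts[arm] = (n_dev, n_risk)
            (a, na), (c, nc) = counts[arm_levels[0]], counts[arm_levels[1]]
            if min(na, nc) == 0:
                or_, lo, hi, flagged, p = np.nan, np.nan, np.nan, False, np.nan
            else:
                or_, lo, hi, flagged = _odds_ratio_2x2(a, na - a, c, nc - c)
                p = _chi2_p(np.array([[a, na - a], [c, nc - c]]))
            rows.append({
                "symptom": symptom, "severity": label, "cutoff": cutoff,
                f"n_at_risk_{arm_levels[0]}": na, f"developed_{arm_levels[0]}": a,
                f"prop_{arm_levels[0]}": a / na if na else np.nan,
                f"n_at_risk_{arm_levels[1]}": nc, f"developed_{arm_levels[1]}": c,
                f"prop_{arm_levels[1]}": c / nc if nc else np.nan,
                "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
                "p_value": p, "zero_cell_corrected": flagged,
            })
    return pd.DataFrame(rows)
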
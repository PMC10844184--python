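"""Quality-adjusted progression-free survival (QAPFS).

Each patient's PFS time (months, censored at last follow-up) is multiplied
by a per-patient quality-adjustment metric — the mean QLQ-C30 summary
score divided by 100, or the mean QLU-C10D utility — averaged over all of
that patient's available on-protocol assessments including baseline.
Group-level QAPFS is the Kaplan-Meier mean of the quality-adjusted times,
implemented as the restricted mean (area under the KM curve up to the
largest observed time), with a Greenwood-based variance for the CI.  The
between-group difference is estimated by resampling patients with
replacement within arm (percentile bootstrap).

Censoring times are quality-adjusted exactly like event times so the KM
risk sets stay internally consistent.  Quality metrics below zero
(worse-than-dead utilities) propagate to negative quality-adjusted times
with a warning; ``floor_at_zero=True`` clips them instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, InsufficientDataError
from .scoring import SUMMARY_DOMAIN

__all__ = [
    "km_restricted_mean",
    "patient_quality_metrics",
    "patient_qapfs",
    "group_qapfs",
    "bootstrap_difference",
    "unadjusted_pfs",
]

MIN_BOOTSTRAP = 1000


def km_restricted_mean(times, events):
    """Kaplan-Meier restricted mean and its Greenwood-based standard error.

    The mean is the area under the KM curve up to the largest observed
    time (event or censored); tied events precede censorings.  With no
    censoring this equals the arithmetic mean exactly.

    Returns ``(mean, se)``.  Raises :class:`InsufficientDataError` when no
    event is observed (the mean is then undefined).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = times.size
    if n == 0:
        raise InsufficientDataError("no observations")
    if not events.any():
        raise InsufficientDataError("all times censored; KM mean undefined")

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    tau = t_sorted[-1]

    ev_times = t_sorted[e_sorted]
    uniq, counts = np.unique(ev_times, return_counts=True)
    # number at risk just before each event time (censored at t still at risk)
    n_risk = n - np.searchsorted(t_sorted, uniq, side="left")
    frac = 1.0 - counts / n_risk
    surv = np.cumprod(frac)  # S(t) just after each unique event time

    # integrate: S = 1 on [t_min, first event), steps afterwards
    t_min = t_sorted[0]
    knots = np.concatenate(([t_min], uniq, [tau]))
    s_vals = np.concatenate(([1.0], surv))  # S on [knots[i], knots[i+1])
    widths = np.diff(knots)
    mean = t_min + float(np.sum(s_vals * widths))

    # Greenwood-type variance of the restricted mean:
    #   sum_j A_j^2 * d_j / (n_j (n_j - d_j)),  A_j = integral_{t_j}^{tau} S dt
    seg = s_vals[1:] * widths[1:]  # area on [uniq[j], next knot)
    area_after = np.concatenate((np.cumsum(seg[::-1])[::-1], [0.0]))[:-1] if seg.size else np.array([])
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n_risk * (n_risk - counts)
        terms = np.where(denom > 0, area_after**2 * counts / np.where(denom > 0, denom, 1), 0.0)
    var = float(np.sum(terms))
    return mean, float(np.sqrt(var))


def patient_quality_metrics(domain_scores: pd.DataFrame, metric: str = "summary",
                            utilities: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-patient quality-adjustment metric.

    ``metric="summary"`` averages each patient's QLQ-C30 summary scores
    over available assessments and divides by 100; ``metric="qlu_c10d"``
    averages the utilities table (``patient_id, visit_month, utility``).

    Returns ``patient_id, metric_value, n_assessments``; patients with no
    scored assessment are absent (callers log them as excluded).
    """
    if metric == "summary":
        sub = domain_scores[domain_scores["domain_id"] == SUMMARY_DOMAIN]
        vals = sub.dropna(subset=["score"]).groupby("patient_id")["score"].agg(["mean", "count"])
        vals["metric_value"] = vals["mean"] / 100.0
    elif metric == "qlu_c10d":
        if utilities is None:
            raise ConfigurationError("metric='qlu_c10d' requires the utilities table")
        vals = utilities.dropna(subset=["utility"]).groupby("patient_id")["utility"].agg(["mean", "count"])
        vals["metric_value"] = vals["mean"]
    else:
        raise ConfigurationError(f"unknown metric {metric!r}")
    out = vals.reset_index()[["patient_id", "metric_value", "count"]]
    return out.rename(columns={"count": "n_assessments"})


def patient_qapfs(survival: pd.DataFrame, metrics: pd.DataFrame,
                  floor_at_zero: bool = False):
    """Quality-adjust each patient's PFS time.

    ``qa_months = pfs_months * metric_value``; the event indicator is
    carried through unchanged.  Patients with no metric (no scored
    assessment) are excluded and reported.

    Returns ``(qa_table, excluded)`` where ``qa_table`` has columns
    ``patient_id, arm, qa_months, event`` and ``excluded`` lists dropped
    patients with reasons.
    """
    merged = survival.merge(metrics, on="patient_id", how="left")
    missing = merged["metric_value"].isna()
    excluded = [
        {"patient_id": pid, "reason": "no scored assessment"}
        for pid in merged.loc[missing, "patient_id"]
    ]
    kept = merged[~missing].copy()
    kept["qa_months"] = kept["pfs_months"] * kept["metric_value"]
    if (kept["qa_months"] < 0).any():
        n_neg = int((kept["qa_months"] < 0).sum())
        if floor_at_zero:
            kept.loc[kept["qa_months"] < 0, "qa_months"] = 0.0
        else:
            warnings.warn(
                f"{n_neg} patient(s) have negative quality-adjusted time "
                "(worse-than-dead utility); retained unfloored",
                stacklevel=2,
            )
    qa = kept[["patient_id", "arm", "qa_months", "event"]].reset_index(drop=True)
    return qa, excluded


def group_qapfs(qa: pd.DataFrame, time_col: str = "qa_months") -> pd.DataFrame:
    """Per-arm KM mean of (quality-adjusted) survival time with 95% CI.

    CI is the normal interval from the Greenwood-based SE of the
    restricted mean.  Requires at least 2 patients and at least one event
    per arm.
    """
    rows = []
    for arm, grp in qa.groupby("arm", sort=False):
        if len(grp) < 2:
            raise InsufficientDataError(f"arm {arm!r} has fewer than 2 patients")
        mean, se = km_restricted_mean(grp[time_col].to_numpy(), grp["event"].to_numpy())
        rows.append(
            {
                "arm": arm,
                "n": len(grp),
                "mean_months": mean,
                "se": se,
                "ci_low": mean - 1.959963984540054 * se,
                "ci_high": mean + 1.959963984540054 * se,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_difference(qa: pd.DataFrame, arm_a, arm_b, n_boot: int = 2000,
                         seed: int | None = None, time_col: str = "qa_months"):
    """Bootstrap the between-arm difference in KM mean (arm_a - arm_b).

    Patients are resampled with replacement within arm; the KM restricted
    mean is recomputed per replicate.  Returns the point estimate (on the
    full sample), the percentile 95% CI, and a two-sided bootstrap p-value
    ``2 * min(P(diff <= 0), P(diff >= 0))`` floored at ``2 / n_boot``.
    Replicates in which an arm has no event are redrawn (counted in
    ``n_degenerate``).
    """
    if n_boot < MIN_BOOTSTRAP:
        raise ConfigurationError(f"n_boot must be >= {MIN_BOOTSTRAP}")
    rng = np.random.default_rng(seed)

    def arm_arrays(arm):
        grp = qa[qa["arm"] == arm]
        if len(grp) < 2:
            raise InsufficientDataError(f"arm {arm!r} has fewer than 2 patients")
        return grp[time_col].to_numpy(dtype=float), grp["event"].to_numpy(dtype=bool)

    ta, ea = arm_arrays(arm_a)
    tb, eb = arm_arrays(arm_b)
    point = km_restricted_mean(ta, ea)[0] - km_restricted_mean(tb, eb)[0]

    diffs = np.empty(n_boot)
    n_degenerate = 0
    for i in range(n_boot):
        while True:
            ia = rng.integers(0, ta.size, ta.size)
            ib = rng.integers(0, tb.size, tb.size)
            if ea[ia].any() and eb[ib].any():
                break
            n_degenerate += 1
        diffs[i] = km_restricted_mean(ta[ia], ea[ia])[0] - km_restricted_mean(tb[ib], eb[ib])[0]

    ci_low, ci_high = np.percentile(diffs, [2.5, 97.5])
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    p = max(min(p, 1.0), 2.0 / n_boot)
    return {
        "difference": float(point),
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "p_value": float(p),
        "n_boot": n_boot,
        "n_degenerate": n_degenerate,
        "boot_mean": float(diffs.mean()),
    }


def unadjusted_pfs(survival: pd.DataFrame) -> pd.DataFrame:
    """Per-arm KM mean of raw PFS (quality metric identically 1); the
    comparator row alongside QAPFS."""
    if survival.empty:
        raise InsufficientDataError("empty survival table")
    df = survival.rename(columns={"pfs_months": "qa_months"})
    return group_qapfs(df[["patient_id", "arm", "qa_months", "event"]])
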
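"""Longitudinal analyses: mixed-model change-from-baseline contrasts with
MID interpretation, per-patient average comparison, pattern-mixture
dropout diagnostics, and questionnaire completion rates.

The change model is a mixed model for repeated measures (MMRM): response
is change from baseline at each post-baseline visit, with categorical
time, treatment arm, their interaction, and country as fixed effects and
a random intercept per patient (REML).  Dropout is handled as missing at
random by the likelihood; no imputation.  Per-timepoint arm contrasts are
adjusted mean differences with country effects averaged over the observed
country distribution.

Statistically significant contrasts are additionally labelled clinically
relevant when the estimate magnitude reaches the domain's minimal
important difference (MID); MIDs ship in ``data/mid_thresholds.tsv``.

Pattern-mixture diagnostics stratify patients by dropout time (early:
off protocol by 8 months; late: still on study at 10 months; never:
on protocol at end of study) and compare score levels across strata
within each arm — a negative early-vs-late contrast indicates
non-ignorable (MNAR-type) dropout.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigurationError, InsufficientDataError
from .scoring import SUMMARY_DOMAIN

__all__ = [
    "load_mid_thresholds",
    "fit_change_model",
    "average_per_patient_comparison",
    "pattern_mixture",
    "dropout_strata",
    "completion_rate",
    "analysis_horizon",
]

_Z = 1.959963984540054


def load_mid_thresholds(path=None) -> pd.DataFrame:
    """MID lookup table (``domain_id, between_group_mid, within_group_mid,
    sensitivity_mid, source``); the packaged defaults carry the
    prespecified summary-score MID of 10 points, the recommended
    myeloma-module and neurotoxicity MIDs, and representative
    small-difference thresholds for the core-questionnaire domains."""
    if path is None:
        with resources.files("qapro.data").joinpath("mid_thresholds.tsv").open() as fh:
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def _mixedlm_fit(formula, data, groups):
    """REML mixed-model fit with an OLS fallback on singular fits."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, data, groups=data[groups])
            res = model.fit(reml=True)
            if not np.all(np.isfinite(res.fe_params)) or not res.converged:
                raise ValueError("non-converged")
            names = list(res.fe_params.index)
            cov = np.asarray(res.cov_params().loc[names, names])
            return res.fe_params, pd.DataFrame(cov, index=names, columns=names), "mixed"
        except Exception:
            ols = smf.ols(formula, data).fit()
            warnings.warn("mixed model singular; downgraded to independent-errors model")
            return ols.params, ols.cov_params(), "ols"


def _cell_vector(names, time, arm, country_weights, ref_time, ref_arm):
    """Design vector for the adjusted mean of one (time, arm) cell."""
    v = pd.Series(0.0, index=names)
    v["Intercept"] = 1.0
    tname = f"C(visit_month)[T.{time}]"
    if time != ref_time and tname in v.index:
        v[tname] = 1.0
    aname = f"C(arm)[T.{arm}]"
    if arm != ref_arm and aname in v.index:
        v[aname] = 1.0
        iname = f"C(visit_month)[T.{time}]:C(arm)[T.{arm}]"
        if time != ref_time and iname in v.index:
            v[iname] = 1.0
    for cname, w in country_weights.items():
        if cname in v.index:
            v[cname] = w
    return v


def fit_change_model(domain_scores: pd.DataFrame, survival: pd.DataFrame,
                     domain_id: str = SUMMARY_DOMAIN, baseline_month: int = 0,
                     max_month: int = 8, alpha: float = 0.05,
                     mid: float | None = None) -> pd.DataFrame:
    """MMRM on change from baseline, with per-timepoint arm contrasts.

    Parameters
    ----------
    domain_scores
        Long score table from :func:`qapro.scoring.score_items`.
    survival
        Per-patient table with ``patient_id, arm`` and optionally
        ``country``.
    domain_id, baseline_month, max_month
        Which domain to model and the analysis window (post-baseline
        visits up to ``max_month``).
    alpha
        Significance level for the contrast flags (0.05 by default; some
        analysis plans reserve 0.01 for a primary endpoint).
    mid
        Minimal important difference for the clinical-relevance flag;
        looked up from the packaged MID table when omitted.

    Returns
    -------
    One row per post-baseline timepoint with within-arm adjusted mean
    changes (and CIs/p-values) and the between-arm difference with CI,
    p-value, ``statistically_significant`` and ``clinically_relevant``
    flags (the latter evaluated only for significant contrasts).
    """
    arms = list(pd.unique(survival["arm"]))
    if len(arms) != 2:
        raise ConfigurationError(f"need exactly 2 arms, got {arms}")
    if mid is None:
        mids = load_mid_thresholds()
        hit = mids.loc[mids["domain_id"] == domain_id, "between_group_mid"]
        mid = float(hit.iloc[0]) if len(hit) else np.nan

    sub = domain_scores[domain_scores["domain_id"] == domain_id]
    wide = sub.pivot_table(index="patient_id", columns="visit_month", values="score")
    if baseline_month not in wide.columns:
        raise InsufficientDataError("no baseline scores")
    post_months = sorted(m for m in wide.columns if baseline_month < m <= max_month)
    long = (
        wide[post_months]
        .sub(wide[baseline_month], axis=0)
        .stack()
        .rename("change")
        .reset_index()
    )
    cols = ["patient_id", "arm"] + (["country"] if "country" in survival else [])
    data = long.merge(survival[cols], on="patient_id").dropna(subset=["change"])
    for arm in arms:
        if data.loc[data["arm"] == arm, "visit_month"].nunique() < 2:
            raise InsufficientDataError(f"arm {arm!r} has data at fewer than 2 post-baseline visits")

    use_country = "country" in data and data["country"].nunique() > 1
    formula = "change ~ C(visit_month) * C(arm)" + (" + C(country)" if use_country else "")
    params, cov, model_kind = _mixedlm_fit(formula, data, "patient_id")
    names = list(params.index)

    ref_arm = sorted(arms)[0]
    alt_arm = [a for a in arms if a != ref_arm][0]
    ref_time = post_months[0]
    country_weights = {}
    if use_country:
        freqs = data["country"].value_counts(normalize=True)
        for c, w in freqs.items():
            country_weights[f"C(country)[T.{c}]"] = float(w)

    def estimate(v):
        est = float(v @ params)
        se = float(np.sqrt(v @ cov.values @ v))
        p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        return est, se, p

    rows = []
    for t in post_months:
        v_ref = _cell_vector(names, t, ref_arm, country_weights, ref_time, ref_arm)
        v_alt = _cell_vector(names, t, alt_arm, country_weights, ref_time, ref_arm)
        e_ref, se_ref, p_ref = estimate(v_ref)
        e_alt, se_alt, p_alt = estimate(v_alt)
        diff, se_d, p_d = estimate(v_alt - v_ref)
        significant = bool(p_d < alpha)
        rows.append({
            "domain_id": domain_id, "timepoint_months": t, "model": model_kind,
            f"change_{ref_arm}": e_ref,
            f"change_{ref_arm}_ci_low": e_ref - _Z * se_ref,
            f"change_{ref_arm}_ci_high": e_ref + _Z * se_ref,
            f"change_{ref_arm}_p": p_ref,
            f"change_{alt_arm}": e_alt,
            f"change_{alt_arm}_ci_low": e_alt - _Z * se_alt,
            f"change_{alt_arm}_ci_high": e_alt + _Z * se_alt,
            f"change_{alt_arm}_p": p_alt,
            "difference": diff,
            "difference_direction": f"{alt_arm} - {ref_arm}",
            "difference_ci_low": diff - _Z * se_d,
            "difference_ci_high": diff + _Z * se_d,
            "p_value": p_d,
            "mid": mid,
            "statistically_significant": significant,
            "clinically_relevant": bool(significant and np.isfinite(mid) and abs(diff) >= mid),
        })
    return pd.DataFrame(rows)


def average_per_patient_comparison(domain_scores: pd.DataFrame, survival: pd.DataFrame,
                                   domain_id: str = SUMMARY_DOMAIN) -> dict:
    """Compare the per-patient average score between arms (rank-sum test).

    Each patient contributes the mean of all their available scored
    assessments (a single assessment is its own average).  Returns
    per-arm means/SDs and the two-sided Wilcoxon rank-sum p-value.
    """
    sub = domain_scores[(domain_scores["domain_id"] == domain_id)].dropna(subset=["score"])
    per_patient = sub.groupby("patient_id")["score"].mean().rename("avg").reset_index()
    merged = per_patient.merge(survival[["patient_id", "arm"]], on="patient_id")
    arms = list(pd.unique(merged["arm"]))
    if len(arms) != 2:
        raise ConfigurationError(f"need exactly 2 arms, got {arms}")
    a = merged.loc[merged["arm"] == arms[0], "avg"].to_numpy()
    b = merged.loc[merged["arm"] == arms[1], "avg"].to_numpy()
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "arms": arms,
        f"mean_{arms[0]}": float(a.mean()), f"sd_{arms[0]}": float(a.std(ddof=1)),
        f"mean_{arms[1]}": float(b.mean()), f"sd_{arms[1]}": float(b.std(ddof=1)),
        "n": {arms[0]: int(a.size), arms[1]: int(b.size)},
        "statistic": float(stat),
        "p_value": float(p),
    }


def dropout_strata(survival: pd.DataFrame, early_cutoff: float = 8,
                   late_entry: float = 10, end_of_study: float = 22) -> pd.Series:
    """Classify dropout pattern from the last on-protocol visit.

    ``early``: off protocol by ``early_cutoff`` months; ``never``: still
    on protocol at ``end_of_study``; ``late``: everyone in between (on
    study at ``late_entry`` months).
    """
    last = survival.set_index("patient_id")["last_followup_month"]
    strata = pd.Series("late", index=last.index, name="stratum")
    strata[last <= early_cutoff] = "early"
    strata[last >= end_of_study] = "never"
    return strata


def pattern_mixture(domain_scores: pd.DataFrame, survival: pd.DataFrame,
                    domain_id: str = SUMMARY_DOMAIN, early_cutoff: float = 8,
                    late_entry: float = 10, end_of_study: float = 22) -> pd.DataFrame:
    """Pattern-mixture dropout diagnostics per arm.

    Within each arm, a mixed model of the score on dropout stratum and
    categorical time (random intercept per patient) estimates the mean
    score difference between strata.  Both the 2-stratum (early vs late,
    where "late" pools everyone on study at 10 months) and the 3-stratum
    (early / late / never) versions are emitted.  Empty strata produce a
    skipped-contrast row with a warning.
    """
    strata = dropout_strata(survival, early_cutoff, late_entry, end_of_study)
    sub = domain_scores[domain_scores["domain_id"] == domain_id].dropna(subset=["score"])
    data = sub.merge(survival[["patient_id", "arm"]], on="patient_id")
    data["stratum3"] = data["patient_id"].map(strata)
    data["stratum2"] = np.where(data["stratum3"] == "early", "early", "late")
    rows = []
    for arm, grp in data.groupby("arm", sort=False):
        for version, col, pairs in (
            ("2-stratum", "stratum2", [("early", "late")]),
            ("3-stratum", "stratum3", [("early", "late"), ("early", "never"), ("late", "never")]),
        ):
            present = set(grp[col].unique())
            for s_a, s_b in pairs:
                if s_a not in present or s_b not in present:
                    warnings.warn(f"{arm}/{version}: stratum {s_a!r} or {s_b!r} empty; "
                                  "contrast not estimable")
                    rows.append({"arm": arm, "version": version, "contrast": f"{s_a}-{s_b}",
                                 "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                                 "p_value": np.nan, "estimable": False})
                    continue
                d = grp[grp[col].isin([s_a, s_b])].copy()
                use_time = d["visit_month"].nunique() > 1
                formula = f"score ~ C({col}, Treatment(reference='{s_b}'))"
                if use_time:
                    formula += " + C(visit_month)"
                params, cov, _ = _mixedlm_fit(formula, d, "patient_id")
                cname = f"C({col}, Treatment(reference='{s_b}'))[T.{s_a}]"
                est = float(params[cname])
                se = float(np.sqrt(cov.loc[cname, cname]))
                p = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
                rows.append({"arm": arm, "version": version, "contrast": f"{s_a}-{s_b}",
                             "estimate": est, "ci_low": est - _Z * se,
                             "ci_high": est + _Z * se, "p_value": p, "estimable": True})
    return pd.DataFrame(rows)


def completion_rate(domain_scores: pd.DataFrame, survival: pd.DataFrame,
                    visit_months, domain_id: str = SUMMARY_DOMAIN) -> pd.DataFrame:
    """Questionnaire completion rate per visit.

    Numerator: randomized patients with enough completed items to compute
    the summary score at that visit; denominator: patients on protocol
    (``last_followup_month >= visit``).  The ``overall`` row pools visits.
    """
    scored = domain_scores[(domain_scores["domain_id"] == domain_id)
                           & domain_scores["score"].notna()]
    scored_sets = scored.groupby("visit_month")["patient_id"].apply(set).to_dict()
    last = survival.set_index("patient_id")["last_followup_month"]
    rows, num_tot, den_tot = [], 0, 0
    for v in visit_months:
        on_protocol = set(last[last >= v].index)
        num = len(scored_sets.get(v, set()) & on_protocol)
        den = len(on_protocol)
        rows.append({"visit_month": v, "n_scored": num, "n_on_protocol": den,
                     "completion_pct": 100.0 * num / den if den else np.nan})
        num_tot += num
        den_tot += den
    rows.append({"visit_month": "overall", "n_scored": num_tot, "n_on_protocol": den_tot,
                 "completion_pct": 100.0 * num_tot / den_tot if den_tot else np.nan})
    return pd.DataFrame(rows)


def analysis_horizon(survival: pd.DataFrame, visit_months, min_per_arm: int = 15):
    """Last follow-up visit before the number of on-protocol patients in
    either arm falls below ``min_per_arm``."""
    last = survival.set_index("patient_id")["last_followup_month"]
    arm = survival.set_index("patient_id")["arm"]
    horizon = None
    for v in sorted(visit_months):
        on = last[last >= v]
        counts = arm.loc[on.index].value_counts()
        if len(counts) < survival["arm"].nunique() or (counts < min_per_arm).any():
            break
        horizon = v
    if horizon is None:
        raise InsufficientDataError("no visit satisfies the on-protocol minimum")
    return horizon
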
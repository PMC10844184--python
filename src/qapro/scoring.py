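"""Questionnaire scoring: EORTC QLQ-C30 / QLQ-MY20 domains, the QLQ-C30
summary score, and the FACT/GOG-Ntx neurotoxicity subscale.

EORTC scoring follows the standard linear transformation: the raw score RS
is the mean of the answered items of a domain, and

* functional domains:  ``100 * (1 - (RS - 1) / range)``
* symptom domains and global health status:  ``100 * ((RS - 1) / range)``

where ``range`` is 3 for 4-point items and 6 for the 7-point global health
items.  A domain is scored only when at least half of its items were
answered (the half rule).  The summary score is the mean of 13 of the 15
QLQ-C30 domains (global health status and financial difficulties excluded)
after reversing symptom domains so that 100 is always best.

The FACT/GOG-Ntx subscale reverses each 0-4 item (``4 - response``), sums
the answered items and prorates by ``11 / n_answered``; it is scored only
when at least 6 of the 11 items were answered.

Item-to-domain maps are shipped as a versioned instrument specification
file (``data/instrument_spec.tsv``) rather than hard-coded.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ._errors import InvalidResponseError

__all__ = [
    "load_instrument_spec",
    "raw_item_to_0_100",
    "score_domain",
    "summary_score",
    "fact_ntx_score",
    "score_items",
    "SUMMARY_DOMAIN",
    "FACT_DOMAIN",
]

SUMMARY_DOMAIN = "summary"
FACT_DOMAIN = "fact_ntx"

#: 0-100 equivalents of the four EORTC response levels, as used for
#: symptom dichotomization thresholds (integers by convention).
_RAW_0_100 = {1: 0, 2: 33, 3: 67, 4: 100}


def load_instrument_spec(path=None) -> pd.DataFrame:
    """Load the instrument specification table.

    Columns: ``instrument, domain_id, item_id, direction, item_range,
    summary_eligible``.  With ``path=None`` the packaged specification
    (QLQ-C30 v3, QLQ-MY20, FACT/GOG-Ntx) is returned.
    """
    if path is None:
        with resources.files("qapro.data").joinpath("instrument_spec.tsv").open() as fh:
            spec = pd.read_csv(fh, sep="\t")
    else:
        spec = pd.read_csv(path, sep="\t")
    spec["summary_eligible"] = spec["summary_eligible"].map(
        {"yes": True, "no": False, True: True, False: False}
    )
    dup = spec.duplicated(subset=["instrument", "item_id"])
    if dup.any():
        raise ValueError(f"items mapped to more than one domain: {spec.loc[dup, 'item_id'].tolist()}")
    return spec


def raw_item_to_0_100(response: int) -> int:
    """Map a 4-point Likert response to its printed 0-100 equivalent.

    ``1 -> 0, 2 -> 33, 3 -> 67, 4 -> 100``.  These integer values are the
    conventional thresholds used for symptom dichotomization; domain
    scoring uses the exact (unrounded) linear transform instead.
    """
    try:
        return _RAW_0_100[int(response)]
    except (KeyError, ValueError, TypeError):
        raise InvalidResponseError(f"response {response!r} not in 1-4") from None


def score_domain(responses, direction: str, item_range: int, n_items: int | None = None):
    """Score one EORTC domain from its item responses.

    Parameters
    ----------
    responses
        Item responses for every item of the domain; missing items as
        ``None``/NaN.  Valid levels are ``1 .. item_range + 1``.
    direction
        ``"functional"``, ``"symptom"`` or ``"ghs"``.
    item_range
        3 for 4-point items, 6 for the 7-point global health items.
    n_items
        Number of items the domain has; defaults to ``len(responses)``.

    Returns
    -------
    (score, n_answered)
        ``score`` is NaN when fewer than half of the items were answered.
    """
    arr = np.asarray([np.nan if r is None else r for r in responses], dtype=float)
    if n_items is None:
        n_items = len(arr)
    answered = arr[~np.isnan(arr)]
    bad = (answered < 1) | (answered > item_range + 1)
    if bad.any():
        raise InvalidResponseError(
            f"responses {answered[bad].tolist()} outside 1-{item_range + 1}"
        )
    n_answered = answered.size
    if n_answered == 0 or 2 * n_answered < n_items:
        return np.nan, int(n_answered)
    rs = answered.mean()
    if direction == "functional":
        score = 100.0 * (1.0 - (rs - 1.0) / item_range)
    elif direction in ("symptom", "ghs"):
        score = 100.0 * (rs - 1.0) / item_range
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(score), int(n_answered)


def summary_score(domain_scores: dict, spec: pd.DataFrame | None = None,
                  min_domains: int = 13) -> float:
    """QLQ-C30 summary score from the 15 domain scores.

    Symptom domains are reversed (``100 - score``) so higher means better,
    then the 13 summary-eligible domains (all but global health status and
    financial difficulties) are averaged.  By default all 13 must be
    present; ``min_domains`` below 13 enables a relaxed mode averaging the
    available eligible domains.
    """
    if spec is None:
        spec = load_instrument_spec()
    dom = spec[spec["instrument"] == "QLQC30"].drop_duplicates("domain_id")
    values = []
    for _, row in dom[dom["summary_eligible"]].iterrows():
        s = domain_scores.get(row["domain_id"], np.nan)
        if s is None or (isinstance(s, float) and np.isnan(s)):
            continue
        values.append(100.0 - s if row["direction"] == "symptom" else float(s))
    if len(values) < min_domains:
        return np.nan
    return float(np.mean(values))


def fact_ntx_score(responses, min_answered: int = 6):
    """FACT/GOG-Ntx subscale (0-44, higher = less neuropathy).

    Each 0-4 item is reversed (``4 - response``); the subscale is the sum
    of reversed answered items prorated by ``11 / n_answered``, scored only
    when at least ``min_answered`` (default 6, i.e. >= 50%) of the 11 items
    were answered.
    """
    arr = np.asarray([np.nan if r is None else r for r in responses], dtype=float)
    answered = arr[~np.isnan(arr)]
    if ((answered < 0) | (answered > 4)).any():
        raise InvalidResponseError("FACT responses must lie in 0-4")
    n_answered = answered.size
    if n_answered < min_answered:
        return np.nan, int(n_answered)
    score = (4.0 - answered).sum() * 11.0 / n_answered
    return float(score), int(n_answered)


def score_items(items: pd.DataFrame, spec: pd.DataFrame | None = None,
                min_summary_domains: int = 13) -> pd.DataFrame:
    """Score a long-format item-response table into domain scores.

    Parameters
    ----------
    items
        Columns ``patient_id, visit_month, instrument, item_id, response``;
        a missing item may be an absent row or a NaN response.
    spec
        Instrument specification; defaults to the packaged one.
    min_summary_domains
        Completeness requirement for the summary score (13 = strict).

    Returns
    -------
    Long table ``patient_id, visit_month, domain_id, score,
    n_items_answered`` including the ``summary`` and ``fact_ntx`` rows.
    """
    if spec is None:
        spec = load_instrument_spec()
    items = items.copy()
    items["response"] = pd.to_numeric(items["response"], errors="coerce")

    key = ["patient_id", "visit_month", "instrument", "item_id"]
    if items.duplicated(subset=key).any():
        raise ValueError("duplicate (patient, visit, instrument, item) rows")

    merged = items.merge(spec, on=["instrument", "item_id"], how="left", validate="m:1")
    unknown = merged["domain_id"].isna()
    if unknown.any():
        bad = merged.loc[unknown, ["instrument", "item_id"]].drop_duplicates()
        raise ValueError(f"unmapped items: {bad.to_dict('records')}")
    out_of_range = (
        merged["response"].notna()
        & (
            np.where(merged["direction"] == "fact", merged["response"] < 0, merged["response"] < 1)
            | (merged["response"] > merged["item_range"] + np.where(merged["direction"] == "fact", 0, 1))
        )
    )
    if out_of_range.any():
        bad = merged.loc[out_of_range, key + ["response"]].head()
        raise InvalidResponseError(f"responses outside declared range, e.g. {bad.to_dict('records')}")

    n_items_per_domain = spec.groupby("domain_id")["item_id"].size()

    g = merged.groupby(["patient_id", "visit_month", "domain_id"], sort=False)
    agg = g.agg(
        rs=("response", "mean"),
        n_answered=("response", "count"),
        direction=("direction", "first"),
        item_range=("item_range", "first"),
    ).reset_index()
    agg["n_items"] = agg["domain_id"].map(n_items_per_domain)

    is_fact = agg["direction"] == "fact"
    half_ok = 2 * agg["n_answered"] >= agg["n_items"]
    # EORTC transform
    func = 100.0 * (1.0 - (agg["rs"] - 1.0) / agg["item_range"])
    symp = 100.0 * (agg["rs"] - 1.0) / agg["item_range"]
    score = np.where(agg["direction"] == "functional", func, symp)
    # FACT proration: sum of reversed answered items * 11 / n_answered
    fact = (4.0 - agg["rs"]) * 11.0
    score = np.where(is_fact, fact, score)
    score = np.where(half_ok & agg["rs"].notna(), score, np.nan)
    agg["score"] = score

    out = agg[["patient_id", "visit_month", "domain_id", "score", "n_answered"]].rename(
        columns={"n_answered": "n_items_answered"}
    )

    # summary score rows
    c30 = spec[spec["instrument"] == "QLQC30"].drop_duplicates("domain_id")
    eligible = c30.loc[c30["summary_eligible"], "domain_id"].tolist()
    sym_doms = set(c30.loc[c30["direction"] == "symptom", "domain_id"])
    sub = out[out["domain_id"].isin(eligible)].copy()
    sub["oriented"] = np.where(sub["domain_id"].isin(sym_doms), 100.0 - sub["score"], sub["score"])
    summ = (
        sub.groupby(["patient_id", "visit_month"])["oriented"]
        .agg(["mean", "count"])
        .reset_index()
    )
    summ["score"] = np.where(summ["count"] >= min_summary_domains, summ["mean"], np.nan)
    summ["domain_id"] = SUMMARY_DOMAIN
    summ = summ.rename(columns={"count": "n_items_answered"})[
        ["patient_id", "visit_month", "domain_id", "score", "n_items_answered"]
    ]

    result = pd.concat([out, summ], ignore_index=True)
    return result.sort_values(["patient_id", "visit_month", "domain_id"]).reset_index(drop=True)
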
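"""Preference-based utilities: QLU-C10D health-state levels and value-set
scoring.

The QLU-C10D descriptive system has 10 dimensions (physical, role, social
and emotional functioning, pain, fatigue, sleep, appetite, nausea, bowel
problems), each on 4 severity levels derived from QLQ-C30 items.  A
country-specific value set assigns a non-negative utility decrement to
each (dimension, level); the utility of a health state is

    u = 1 - sum_d decrement(d, level_d)

so the all-best state scores exactly 1 (full health), zero anchors the
state of being dead, and severely burdened states may fall below zero.

The engine is value-set-agnostic: any table satisfying the structural
invariants (10 dimensions x 4 levels, level-1 decrement 0, decrements
non-negative and non-decreasing in level) can be plugged in.  The packaged
file ``qlu_c10d_valueset_synthetic.tsv`` is a SYNTHETIC value set with
those invariants, constructed for testing and demonstration; substitute a
published country tariff for substantive work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._errors import InvalidLevelError

__all__ = [
    "ValueSet",
    "load_value_set",
    "items_to_dimension_levels",
    "utility_from_levels",
    "utility_scores",
]

N_DIMENSIONS = 10
N_LEVELS = 4


@dataclass
class ValueSet:
    """A QLU-C10D-style value set.

    Attributes
    ----------
    name
        Label, e.g. the country of the valuation study.
    item_map
        dimension -> list of QLQ-C30 item ids that define it.
    decrements
        dimension -> array of 4 utility decrements (levels 1..4).
    """

    name: str
    item_map: dict = field(default_factory=dict)
    decrements: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.item_map) != N_DIMENSIONS or len(self.decrements) != N_DIMENSIONS:
            raise ValueError(f"value set must have exactly {N_DIMENSIONS} dimensions")
        for dim, dec in self.decrements.items():
            dec = np.asarray(dec, dtype=float)
            if dec.shape != (N_LEVELS,):
                raise ValueError(f"{dim}: need {N_LEVELS} levels")
            if dec[0] != 0:
                raise ValueError(f"{dim}: level-1 decrement must be 0")
            if (dec < 0).any() or (np.diff(dec) < -1e-12).any():
                raise ValueError(f"{dim}: decrements must be non-negative and non-decreasing")
        best = 1.0 - sum(float(np.asarray(d)[0]) for d in self.decrements.values())
        if best != 1.0:
            raise ValueError("utility of the all-best state must be exactly 1")

    @property
    def dimensions(self):
        return list(self.item_map)

    def to_file(self, path) -> None:
        rows = []
        for dim in self.dimensions:
            for lvl in range(1, N_LEVELS + 1):
                rows.append(
                    {
                        "dimension": dim,
                        "item_ids": ";".join(self.item_map[dim]),
                        "level": lvl,
                        "decrement": float(self.decrements[dim][lvl - 1]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_value_set(path=None, name: str | None = None) -> ValueSet:
    """Load and validate a value-set TSV (columns ``dimension, item_ids,
    level, decrement``).  ``path=None`` loads the packaged synthetic set."""
    if path is None:
        with resources.files("qapro.data").joinpath("qlu_c10d_valueset_synthetic.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        name = name or "synthetic"
    else:
        df = pd.read_csv(path, sep="\t")
        name = name or str(path)
    item_map, decrements = {}, {}
    for dim, grp in df.groupby("dimension", sort=False):
        grp = grp.sort_values("level")
        if list(grp["level"]) != list(range(1, N_LEVELS + 1)):
            raise ValueError(f"{dim}: levels must be exactly 1..{N_LEVELS}")
        item_map[dim] = grp["item_ids"].iloc[0].split(";")
        decrements[dim] = grp["decrement"].to_numpy(dtype=float)
    vs = ValueSet(name=name, item_map=item_map, decrements=decrements)
    vs.validate()
    return vs


def items_to_dimension_levels(responses: dict, value_set: ValueSet) -> dict:
    """Derive the 10 dimension levels from QLQ-C30 item responses.

    ``responses`` maps item_id -> Likert response (1-4; missing items may
    be absent or NaN).  For multi-item dimensions the level is the most
    severe (highest) response among the answered constituent items;
    single-item dimensions pass through.  A dimension whose items are all
    missing gets level NaN (the visit's utility is then absent).
    """
    levels = {}
    for dim, item_ids in value_set.item_map.items():
        vals = [responses.get(i) for i in item_ids]
        vals = [v for v in vals if v is not None and not (isinstance(v, float) and np.isnan(v))]
        if not vals:
            levels[dim] = np.nan
            continue
        if any(v < 1 or v > N_LEVELS for v in vals):
            raise InvalidLevelError(f"{dim}: responses {vals} outside 1-{N_LEVELS}")
        levels[dim] = int(max(vals))
    return levels


def utility_from_levels(levels: dict, value_set: ValueSet) -> float:
    """Utility of a health state: ``1 - sum of decrements``.

    NaN if any dimension level is missing.
    """
    total = 0.0
    for dim in value_set.dimensions:
        lvl = levels.get(dim, np.nan)
        if lvl is None or (isinstance(lvl, float) and np.isnan(lvl)):
            return np.nan
        if not (1 <= lvl <= N_LEVELS) or int(lvl) != lvl:
            raise InvalidLevelError(f"{dim}: level {lvl!r} outside 1-{N_LEVELS}")
        total += float(value_set.decrements[dim][int(lvl) - 1])
    return 1.0 - total


def utility_scores(items: pd.DataFrame, value_set: ValueSet | None = None) -> pd.DataFrame:
    """Compute per patient-visit utilities from long-format QLQ-C30 items.

    Returns a table ``patient_id, visit_month, utility`` (utility NaN when
    some dimension had no answered items at that visit).
    """
    if value_set is None:
        value_set = load_value_set()
    c30 = items[items["instrument"] == "QLQC30"].copy()
    c30["response"] = pd.to_numeric(c30["response"], errors="coerce")
    rows = []
    for (pid, visit), grp in c30.groupby(["patient_id", "visit_month"], sort=False):
        resp = dict(zip(grp["item_id"], grp["response"]))
        levels = items_to_dimension_levels(resp, value_set)
        rows.append(
            {
                "patient_id": pid,
                "visit_month": visit,
                "utility": utility_from_levels(levels, value_set),
            }
        )
    out = pd.DataFrame(rows, columns=["patient_id", "visit_month", "utility"])
    return out.sort_values(["patient_id", "visit_month"]).reset_index(drop=True)
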
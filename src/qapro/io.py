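"""Readers, writers and input validation for the tabular interfaces.

All tabular I/O is plain CSV/TSV (RFC 4180), months as the sole time
unit, full-precision scores.  Validation collects malformed rows with row
references instead of failing fast, and only raises when the malformed
fraction exceeds a configurable limit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import load_instrument_spec

__all__ = [
    "read_items",
    "read_survival",
    "ValidationReport",
    "validate_inputs",
    "file_sha256",
]

ITEM_COLUMNS = ["patient_id", "visit_month", "instrument", "item_id", "response"]
SURVIVAL_COLUMNS = ["patient_id", "arm", "pfs_months", "event", "last_followup_month"]


def read_items(path) -> pd.DataFrame:
    """Long-format item responses; blank response = missing."""
    df = pd.read_csv(path, dtype={"patient_id": str, "instrument": str, "item_id": str})
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    return df


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "arm": str})
    if df["event"].dtype == object:
        df["event"] = df["event"].astype(str).str.lower().isin(["true", "1", "yes"])
    else:
        df["event"] = df["event"].astype(bool)
    return df


@dataclass
class ValidationReport:
    """Collected schema/range/uniqueness violations, with row references."""

    errors: list = field(default_factory=list)
    n_rows_checked: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, file, row, message) -> None:
        self.errors.append({"file": str(file), "row": row, "message": message})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.errors, columns=["file", "row", "message"])


def _validate_items(df: pd.DataFrame, name, spec, report: ValidationReport) -> None:
    missing_cols = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing_cols:
        report.add(name, None, f"missing columns: {missing_cols}")
        return
    report.n_rows_checked += len(df)
    merged = df.merge(spec, on=["instrument", "item_id"], how="left")
    for idx in merged.index[merged["domain_id"].isna()]:
        report.add(name, int(idx), f"unknown item "
                                   f"{merged.loc[idx, 'instrument']}/{merged.loc[idx, 'item_id']}")
    resp = pd.to_numeric(merged["response"], errors="coerce")
    low = np.where(merged["direction"] == "fact", 0, 1)
    high = merged["item_range"] + np.where(merged["direction"] == "fact", 0, 1)
    bad = merged["response"].notna() & merged["domain_id"].notna() & (
        resp.isna() | (resp < low) | (resp > high)
    )
    for idx in merged.index[bad]:
        report.add(name, int(idx),
                   f"response {merged.loc[idx, 'response']!r} outside range for "
                   f"{merged.loc[idx, 'item_id']}")
    dup = df.duplicated(subset=["patient_id", "visit_month", "instrument", "item_id"], keep="first")
    for idx in df.index[dup]:
        report.add(name, int(idx), "duplicate (patient, visit, instrument, item)")


def _validate_survival(df: pd.DataFrame, name, report: ValidationReport) -> None:
    missing_cols = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing_cols:
        report.add(name, None, f"missing columns: {missing_cols}")
        return
    report.n_rows_checked += len(df)
    for idx in df.index[pd.to_numeric(df["pfs_months"], errors="coerce").fillna(-1) < 0]:
        report.add(name, int(idx), f"pfs_months {df.loc[idx, 'pfs_months']!r} invalid")
    dup = df.duplicated(subset=["patient_id"], keep="first")
    for idx in df.index[dup]:
        report.add(name, int(idx), "duplicate patient_id")


def validate_inputs(items_path=None, survival_path=None, spec=None,
                    max_error_fraction: float = 0.05) -> ValidationReport:
    """Validate input files against their declared schemas.

    Violations are collected per file with row references; a
    ``ValueError`` is raised only when the malformed fraction exceeds
    ``max_error_fraction``.
    """
    if spec is None:
        spec = load_instrument_spec()
    report = ValidationReport()
    if items_path is not None:
        _validate_items(read_items(items_path), items_path, spec, report)
    if survival_path is not None:
        _validate_survival(read_survival(survival_path), survival_path, report)
    if report.n_rows_checked and len(report.errors) > max_error_fraction * report.n_rows_checked:
        raise ValueError(
            f"{len(report.errors)} violations in {report.n_rows_checked} rows "
            f"(> {max_error_fraction:.0%}); first: {report.errors[:3]}"
        )
    return report


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
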
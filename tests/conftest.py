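import numpy as np
import pandas as pd
import pytest

from qapro import scoring, simulate


@pytest.fixture(scope="session")
def small_trial():
    """A small two-arm synthetic trial shared across tests."""
    cfg = simulate.TrialConfig(n_active=25, n_control=25, seed=424242)
    return simulate.generate(cfg)


@pytest.fixture(scope="session")
def small_scores(small_trial):
    return scoring.score_items(small_trial.items)


@pytest.fixture(scope="session")
def instrument_spec():
    return scoring.load_instrument_spec()


def make_item_rows(patient_id, visit_month, responses):
    """Long-format rows from {item_id: response}; instrument inferred."""
    rows = []
    for item, resp in responses.items():
        instrument = ("QLQC30" if item.startswith("q")
                      else "QLQMY20" if item.startswith("my") else "FACTGOGNTX")
        rows.append({"patient_id": patient_id, "visit_month": visit_month,
                     "instrument": instrument, "item_id": item, "response": resp})
    return rows


def complete_c30(level=1, ghs_level=None):
    """A complete QLQ-C30 response sheet at a constant level."""
    resp = {f"q{i}": level for i in range(1, 29)}
    resp["q29"] = resp["q30"] = ghs_level if ghs_level is not None else min(level, 7)
    return resp
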
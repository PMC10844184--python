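"""End-to-end orchestration: simulate/load -> score -> utilities ->
responder / QAPFS / longitudinal analyses, with a reproducibility
manifest.

Every run writes a ``manifest.json`` recording input hashes, the config
snapshot, seeds, package version and warnings; reruns with an identical
manifest reproduce identical outputs.  A stage failure keeps the partial
outputs and marks the failure point in the manifest.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from ._errors import ConfigurationError
from .io import file_sha256, read_items, read_survival
from .longitudinal import average_per_patient_comparison, completion_rate, fit_change_model, pattern_mixture
from .qapfs import bootstrap_difference, group_qapfs, patient_qapfs, patient_quality_metrics, unadjusted_pfs
from .responder import classify_changes, kd_symptom_analysis, responder_table, time_to_first_improvement
from .scoring import score_items
from .simulate import TrialConfig, generate
from .utilities import load_value_set, utility_scores

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("score", "utility", "respond", "qapfs", "mmrm", "missing")

RESPONDER_DOMAINS = ["physical", "role", "social", "emotional", "ghs_qol",
                     "body_image", "future_perspectives"]


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    return str(o)


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the configured stages in dependency order.

    ``config`` keys: either ``simulate`` (a :class:`TrialConfig` field
    dict) or ``items``/``survival`` file paths; optional ``value_set``
    path, ``stages`` list, ``metric`` (``summary``/``qlu_c10d``),
    ``n_boot``, ``max_month``, ``end_of_study``, ``alpha``.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "simulate"},
        "inputs": {},
        "stages_completed": [],
        "warnings": [],
        "failure": None,
    }
    caught: list = []

    def save(df: pd.DataFrame, name: str):
        df.to_csv(out / name, index=False)

    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            if "simulate" in config:
                sim_cfg = dict(config["simulate"])
                if seed is not None:
                    sim_cfg.setdefault("seed", seed)
                trial = generate(TrialConfig(**sim_cfg))
                items, survival = trial.items, trial.survival
                save(items, "items.csv")
                save(survival, "survival.csv")
                (out / "truth.json").write_text(
                    json.dumps(trial.truth, indent=2, default=_json_default))
                manifest["inputs"]["simulate"] = {"seed": trial.config.seed}
            else:
                items = read_items(config["items"])
                survival = read_survival(config["survival"])
                manifest["inputs"] = {
                    "items": {"path": str(config["items"]),
                              "sha256": file_sha256(config["items"])},
                    "survival": {"path": str(config["survival"]),
                                 "sha256": file_sha256(config["survival"])},
                }

            visit_months = sorted(items["visit_month"].unique())
            max_month = config.get("max_month", 8)
            end_of_study = config.get("end_of_study", max(visit_months))
            alpha = config.get("alpha", 0.05)
            scores = None
            utilities = None

            for stage in stages:
                if stage == "score":
                    scores = score_items(items)
                    save(scores, "domain_scores.csv")
                elif stage == "utility":
                    vs_path = config.get("value_set")
                    metric = config.get("metric", "summary")
                    if metric == "qlu_c10d" and vs_path is None and "value_set_required" in config:
                        raise ConfigurationError("metric 'qlu_c10d' requires a value-set file")
                    vs = load_value_set(vs_path)
                    utilities = utility_scores(items, vs)
                    save(utilities, "utilities.csv")
                elif stage == "respond":
                    scores = score_items(items) if scores is None else scores
                    cls = classify_changes(scores, domains=RESPONDER_DOMAINS)
                    save(cls, "classifications.csv")
                    save(responder_table(cls, survival), "responder_table.csv")
                    tti, cox = time_to_first_improvement(
                        scores, survival, RESPONDER_DOMAINS, end_of_study)
                    save(tti, "time_to_improvement.csv")
                    save(cox, "time_to_improvement_cox.csv")
                    save(kd_symptom_analysis(items, survival, max_month=max_month),
                         "kd_symptoms.csv")
                elif stage == "qapfs":
                    scores = score_items(items) if scores is None else scores
                    metric = config.get("metric", "summary")
                    metrics = patient_quality_metrics(scores, metric, utilities=utilities)
                    qa, excluded = patient_qapfs(survival, metrics)
                    save(qa, "qapfs_patient.csv")
                    res = group_qapfs(qa)
                    save(res, "qapfs_group.csv")
                    save(unadjusted_pfs(survival), "pfs_group.csv")
                    arms = list(pd.unique(survival["arm"]))
                    boot = bootstrap_difference(qa, arms[0], arms[1],
                                                n_boot=config.get("n_boot", 2000), seed=seed)
                    boot["excluded"] = excluded
                    (out / "qapfs_difference.json").write_text(
                        json.dumps(boot, indent=2, default=_json_default))
                elif stage == "mmrm":
                    scores = score_items(items) if scores is None else scores
                    save(fit_change_model(scores, survival, max_month=max_month, alpha=alpha),
                         "mmrm_summary.csv")
                    avg = average_per_patient_comparison(scores, survival)
                    (out / "average_per_patient.json").write_text(
                        json.dumps(avg, indent=2, default=_json_default))
                elif stage == "missing":
                    scores = score_items(items) if scores is None else scores
                    save(completion_rate(scores, survival, visit_months), "completion_rate.csv")
                    save(pattern_mixture(scores, survival, end_of_study=end_of_study),
                         "pattern_mixture.csv")
                else:
                    raise ConfigurationError(f"unknown stage {stage!r}")
                manifest["stages_completed"].append(stage)
            caught = [str(w.message) for w in wlist]
    except Exception as exc:  # retain partial outputs, mark failure point
        manifest["failure"] = {
            "stage": (stages[len(manifest["stages_completed"])]
                      if len(manifest["stages_completed"]) < len(stages) else None),
            "error": f"{type(exc).__name__}: {exc}",
        }
        manifest["warnings"] = caught
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
        raise
    manifest["warnings"] = caught
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return manifest
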
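"""Longitudinal contrasts and dropout diagnostics.

Fits the mixed model for repeated measures (change from baseline, arm x
time, random patient intercept) on a simulated trial, then shows how the
pattern-mixture diagnostic separates informative (MNAR) from completely
random (MCAR) dropout.
"""

from qapro.longitudinal import fit_change_model, pattern_mixture
from qapro.scoring import score_items
from qapro.simulate import TrialConfig, generate

trial = generate(TrialConfig(seed=3))
scores = score_items(trial.items)

mm = fit_change_model(scores, trial.survival)
cols = ["timepoint_months", "difference", "difference_ci_low", "difference_ci_high",
        "p_value", "statistically_significant", "clinically_relevant"]
print("summary-score contrast (observation - Kd) per timepoint, MID = 10:")
print(mm[cols].round(3).to_string(index=False))
print("\nA significant contrast below the 10-point minimal important difference is")
print("flagged significant but NOT clinically relevant.")

for mechanism in ("mcar", "mnar"):
    t = generate(TrialConfig(dropout_mechanism=mechanism, seed=29))
    pm = pattern_mixture(score_items(t.items), t.survival)
    two = pm[(pm.version == "2-stratum") & pm.estimable]
    print(f"\n{mechanism.upper()} dropout, early-vs-late stratum contrast:")
    print(two[["arm", "estimate", "ci_low", "ci_high", "p_value"]].round(3).to_string(index=False))
print("\nUnder MNAR, early dropouts report clearly worse scores (negative contrast);")
print("under MCAR the contrast is null within noise.")
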
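"""Responder analysis on a simulated trial: who improved, who worsened,
how long until the first improvement.

Improvement/worsening means a change from baseline of at least 20 points
(33 for the single-item body-image domain); patients whose baseline leaves
no room for a full-threshold improvement are excluded from the
time-to-improvement analysis.
"""

from qapro.responder import classify_changes, responder_table, time_to_first_improvement
from qapro.scoring import score_items
from qapro.simulate import TrialConfig, generate

trial = generate(TrialConfig(seed=14))
scores = score_items(trial.items)

cls = classify_changes(scores, domains=["physical", "role", "body_image"])
tab = responder_table(cls, trial.survival, category="improved")
cols = ["domain_id", "visit_month", "prop_improved_Kd", "prop_improved_observation",
        "odds_ratio", "p_value"]
print("proportion improved, per visit (odds ratio Kd vs observation):")
print(tab[tab.visit_month <= 8][cols].round(3).to_string(index=False))

times, cox = time_to_first_improvement(scores, trial.survival,
                                       ["physical", "role", "body_image"],
                                       end_of_study=22)
print("\ntime to first recorded improvement (Cox HR, Kd vs observation,")
print("adjusted for baseline score and country):")
print(cox.round(3).to_string(index=False))
print("\nHR > 1 means the maintenance arm reaches improvement sooner; here the")
print("observation arm recovers faster, matching the generator's recovery slopes.")
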
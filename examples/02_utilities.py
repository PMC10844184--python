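"""Preference-based utilities: QLQ-C30 items -> QLU-C10D health state -> utility.

Loads the packaged (synthetic) value set, derives the 10 dimension levels
with the worst-of rule, and prices three health states.
"""

from qapro.utilities import items_to_dimension_levels, load_value_set, utility_from_levels

vs = load_value_set()
print(f"value set: {vs.name!r}, dimensions: {', '.join(vs.dimensions)}")

perfect = {i: 1 for ids in vs.item_map.values() for i in ids}
levels = items_to_dimension_levels(perfect, vs)
print(f"\nall-best responses  -> utility {utility_from_levels(levels, vs):+.3f} (full health)")

in_pain = dict(perfect)
in_pain["q9"], in_pain["q19"] = 2, 4   # two pain items; worst-of gives level 4
levels = items_to_dimension_levels(in_pain, vs)
print(f"severe pain         -> utility {utility_from_levels(levels, vs):+.3f} "
      f"(decrement {vs.decrements['pain'][3]:.2f} for pain level {levels['pain']})")

worst = {i: 4 for i in perfect}
levels = items_to_dimension_levels(worst, vs)
u = utility_from_levels(levels, vs)
print(f"all-worst responses -> utility {u:+.3f} "
      f"({'worse than dead' if u < 0 else 'above the death anchor'})")
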
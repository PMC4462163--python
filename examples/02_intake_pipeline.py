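"""Scoring a small diet diary.

Builds a two-person, four-day diary against the default registry, splits a
composite food, and prints per-person intakes at each cut-off tier with
energy adjustment and serving classes.
"""

from wholegrain import (
    DiaryOccasion,
    Participant,
    default_registry,
    estimate_all,
    intakes_to_frame,
    split_composites,
)

registry = default_registry()

participants = [
    # id, age, sex, NS-SEC class, survey weight, diary days, energy MJ/d
    Participant("adult_1", 42.0, "female", 2, 1.1, 4, 7.8),
    Participant("teen_1", 15.0, "male", 5, 0.9, 4, 8.5),
]

occasions = [
    DiaryOccasion("adult_1", 1, "BRD001", 72.0),   # two slices wholemeal bread
    DiaryOccasion("adult_1", 2, "BRD002", 61.0),   # toast (cooked form)
    DiaryOccasion("adult_1", 3, "POR002", 180.0),  # made-up porridge
    DiaryOccasion("adult_1", 4, "SANDWICH", 150.0),  # composite, split below
    DiaryOccasion("teen_1", 1, "RTE001", 45.0),    # wholewheat biscuit cereal
    DiaryOccasion("teen_1", 2, "SWT003", 125.0),   # topping yoghurt, < 10 % WG
    DiaryOccasion("teen_1", 3, "XCHIPS", 200.0),   # not a whole-grain food
]

# 40 % of the sandwich's mass is wholemeal bread, the rest is filling.
occasions = split_composites(occasions, {"SANDWICH": [("BRD001", 0.4), ("XFILL", 0.6)]})

intakes = estimate_all(occasions, participants, registry)
print(intakes_to_frame(intakes).round(2).to_string(index=False))
# wg_g_per_day_* columns: whole-grain g/d counting foods at any content,
# >=10 % and >=51 % whole grain (each column can only shrink, never grow).
# wg_g_per_10MJ_* removes differences in total food quantity; serving_class
# bins the any-tier intake into 16 g servings ('0' = absolute non-consumer).
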
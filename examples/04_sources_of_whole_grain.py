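"""Where the whole grain comes from.

On a synthetic survey: the percent of whole-grain eating occasions by food
commodity group within age strata, and the percent of whole-grain grams by
grain type at two cut-off tiers.
"""

import pandas as pd

from wholegrain import (
    CutoffTier,
    SyntheticConfig,
    generate,
    grain_shares,
    occasion_shares,
)

ds = generate(SyntheticConfig(n_participants=2000, seed=5))
people = {p.participant_id: p for p in ds.participants}

# Food-group share of whole-grain eating occasions, adults vs children.
tables = occasion_shares(
    ds.occasions,
    ds.registry,
    strata={pid: ("adult" if p.is_adult else "child_teen") for pid, p in people.items()},
)
df = pd.DataFrame([t.to_series() for t in tables])
print("Percent of whole-grain eating occasions by food group:")
print(df.round(1).to_string())

# Grain-type share of total whole-grain grams.
for tier in (CutoffTier.ANY, CutoffTier.GE51):
    shares = grain_shares(ds.occasions, ds.registry, tier=tier)
    ranked = sorted(shares.items(), key=lambda kv: -kv[1])
    txt = ", ".join(f"{g.value} {v:.0f} %" for g, v in ranked if v >= 0.5)
    print(f"\ngrain shares ({tier.value} tier): {txt}")
# Wheat dominates via bread and breakfast cereals; restricting to foods
# with >=51 % whole grain concentrates the shares further.
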
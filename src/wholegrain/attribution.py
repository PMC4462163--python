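"""Sources of whole grain: food-group and grain-type contributions.

Two complementary views of where whole grain comes from:

* food-group shares — percent of whole-grain *eating occasions* (diary
  rows whose food meets the tier threshold) falling in each of the nine
  commodity groups, optionally per stratum and survey-weighted;
* grain shares — percent of total whole-grain *grams* contributed by each
  grain type.

An eating occasion is one diary row; no co-consumption merging is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .composition import FoodGroup, GrainType, Registry
from .diary import DiaryOccasion
from .pipeline import DEFAULT_TIER_THRESHOLDS, CutoffTier

__all__ = ["AttributionTable", "occasion_shares", "grain_shares"]


@dataclass
class AttributionTable:
    """Food-group occasion shares within one stratum.

    ``food_group_percent`` sums to 100 when ``n_occasions > 0``; an empty
    stratum is flagged with ``n_occasions == 0`` and all-None percents.
    """

    stratum: str
    n_occasions: int
    food_group_percent: dict[FoodGroup, float | None] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        s = pd.Series(
            {g.value: self.food_group_percent.get(g) for g in FoodGroup},
            name=self.stratum,
        )
        s["n_occasions"] = self.n_occasions
        return s


def _tier_threshold(tier: CutoffTier) -> float:
    return DEFAULT_TIER_THRESHOLDS[tier]


def _counts(
    occasions: Iterable[DiaryOccasion],
    registry: Registry,
    tier: CutoffTier,
    weights: Mapping[str, float] | None,
) -> tuple[dict[FoodGroup, float], int]:
    threshold = _tier_threshold(tier)
    totals: dict[FoodGroup, float] = {g: 0.0 for g in FoodGroup}
    n = 0
    for occ in occasions:
        pct = registry.effective_wg_percent(occ.food_code)
        if pct <= 0 or (threshold > 0 and pct < threshold):
            continue
        group = registry.food_group(occ.food_code)
        assert group is not None
        w = 1.0 if weights is None else weights[occ.participant_id]
        totals[group] += w
        n += 1
    return totals, n


def occasion_shares(
    occasions: Sequence[DiaryOccasion],
    registry: Registry,
    strata: Callable[[DiaryOccasion], str] | Mapping[str, str] | None = None,
    tier: CutoffTier = CutoffTier.ANY,
    weights: Mapping[str, float] | None = None,
) -> list[AttributionTable]:
    """Percent of whole-grain eating occasions per food group, by stratum.

    Parameters
    ----------
    strata
        Either a function mapping an occasion to its stratum label, a
        mapping from participant_id to label, or None for a single "all"
        stratum. Strata appear in first-encounter order.
    weights
        Optional survey weights per participant_id applied to occasion
        counts; the default (None) counts occasions unweighted.
    """
    if strata is None:
        label = lambda occ: "all"  # noqa: E731
    elif callable(strata):
        label = strata
    else:
        label = lambda occ: strata[occ.participant_id]  # noqa: E731

    grouped: dict[str, list[DiaryOccasion]] = {}
    for occ in occasions:
        grouped.setdefault(label(occ), []).append(occ)

    out: list[AttributionTable] = []
    for stratum, occs in grouped.items():
        totals, n = _counts(occs, registry, tier, weights)
        grand = sum(totals.values())
        if n == 0 or grand == 0:
            out.append(
                AttributionTable(stratum, 0, {g: None for g in FoodGroup})
            )
        else:
            out.append(
                AttributionTable(
                    stratum,
                    n,
                    {g: 100.0 * v / grand for g, v in totals.items()},
                )
            )
    return out


def grain_shares(
    occasions: Iterable[DiaryOccasion],
    registry: Registry,
    tier: CutoffTier = CutoffTier.ANY,
) -> dict[GrainType, float]:
    """Percent of total whole-grain grams contributed by each grain type.

    Grams are summed over occasions whose food meets the tier threshold
    and normalised to 100. Returns an empty dict when no whole grain was
    consumed at the tier (degenerate input, flagged to the caller by
    emptiness).
    """
    threshold = _tier_threshold(tier)
    grams: dict[GrainType, float] = {}
    for occ in occasions:
        pct = registry.effective_wg_percent(occ.food_code)
        if pct <= 0 or (threshold > 0 and pct < threshold):
            continue
        for grain, g in registry.grain_grams(occ.food_code, occ.consumed_g).items():
            grams[grain] = grams.get(grain, 0.0) + g
    total = sum(grams.values())
    if total == 0:
        return {}
    return {grain: 100.0 * g / total for grain, g in grams.items()}
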
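"""Core intake scoring.

Whole-grain grams of an eating occasion are the consumed mass (mapped to
the registry's uncooked basis where a cooking-loss factor applies) times
the food's whole-grain percentage. Per-person intake is the sum over the
diary divided by the number of diary days, computed at three cut-off tiers
(any content, >=10 %, >=51 % whole grain at the food level), both absolute
(g/d) and energy-adjusted (g per 10 MJ of daily energy intake). Intakes are
also classified into 16 g servings, with exact non-consumers kept as their
own class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .composition import Registry
from .diary import DiaryOccasion, Participant

__all__ = [
    "CutoffTier",
    "ServingDefinition",
    "PipelineConfig",
    "ParticipantIntake",
    "occasion_wg_mass",
    "daily_intake",
    "energy_adjust",
    "daily_from_energy_adjusted",
    "serving_class",
    "estimate_all",
    "intakes_to_frame",
]


class CutoffTier(str, Enum):
    """Minimum food-level whole-grain percentage for an occasion to count."""

    ANY = "any"
    GE10 = "ge10"
    GE51 = "ge51"


DEFAULT_TIER_THRESHOLDS: dict[CutoffTier, float] = {
    CutoffTier.ANY: 0.0,
    CutoffTier.GE10: 10.0,
    CutoffTier.GE51: 51.0,
}


@dataclass(frozen=True)
class ServingDefinition:
    """One serving = 16 g whole grain per day; classes are half-open 16 g bins.

    Class labels: exact zero intake is its own class ("0"); otherwise
    [0, 16) is under one serving, [16, 32) one serving, [32, 48) two, and
    48 g/d or more (three or more servings) is unbounded above.
    """

    grams_per_serving: float = 16.0

    @property
    def boundaries(self) -> tuple[float, float, float]:
        s = self.grams_per_serving
        return (s, 2 * s, 3 * s)

    @property
    def class_labels(self) -> tuple[str, ...]:
        b = self.boundaries
        return (
            "0",
            f"0to<{b[0]:g}",
            f"{b[0]:g}to<{b[1]:g}",
            f"{b[1]:g}to<{b[2]:g}",
            f"{b[2]:g}plus",
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the intake pipeline."""

    tier_thresholds: Mapping[CutoffTier, float] = field(
        default_factory=lambda: dict(DEFAULT_TIER_THRESHOLDS)
    )
    serving: ServingDefinition = ServingDefinition()
    energy_basis_MJ: float = 10.0


@dataclass
class ParticipantIntake:
    """Derived whole-grain intake of one participant.

    ``serving_class`` is based on the default-tier (any content) absolute
    intake, matching how serving proportions are reported.
    """

    participant_id: str
    wg_g_per_day: dict[CutoffTier, float]
    wg_g_per_10MJ: dict[CutoffTier, float]
    serving_class: str
    is_nonconsumer: dict[CutoffTier, bool]


def occasion_wg_mass(occasion: DiaryOccasion, registry: Registry) -> float:
    """Grams of whole grain contributed by one eating occasion.

    Consumed mass is first mapped to the registry basis when the food is a
    cooked form of another record; non-registry foods contribute 0.

    >>> # 50 g of a food containing 40 g whole grain per 100 g -> 20 g
    """
    return float(sum(registry.grain_grams(occasion.food_code, occasion.consumed_g).values()))


def daily_intake(
    occasions: Iterable[DiaryOccasion],
    n_diary_days: int,
    tier: CutoffTier,
    registry: Registry,
    config: PipelineConfig | None = None,
) -> float:
    """Whole-grain intake in g/d for one participant at one cut-off tier.

    Sums occasion whole-grain mass over foods whose effective whole-grain
    percentage meets the tier threshold (strictly positive for the "any"
    tier), then averages over the recorded diary days.
    """
    if n_diary_days <= 0:
        raise ValueError(f"n_diary_days must be positive, got {n_diary_days}")
    cfg = config or PipelineConfig()
    threshold = cfg.tier_thresholds[tier]
    total = 0.0
    for occ in occasions:
        pct = registry.effective_wg_percent(occ.food_code)
        if pct <= 0:
            continue
        if threshold > 0 and pct < threshold:
            continue
        total += occasion_wg_mass(occ, registry)
    return total / n_diary_days


def energy_adjust(
    intake_g_d: float, energy_MJ_per_day: float, basis_MJ: float = 10.0
) -> float:
    """Energy-adjusted intake: grams per ``basis_MJ`` (default 10 MJ) per day.

    >>> energy_adjust(20.0, 8.0)
    25.0
    """
    if not energy_MJ_per_day > 0:
        raise ValueError(f"energy must be > 0, got {energy_MJ_per_day}")
    return intake_g_d * basis_MJ / energy_MJ_per_day


def daily_from_energy_adjusted(
    intake_g_per_basis: float, energy_MJ_per_day: float, basis_MJ: float = 10.0
) -> float:
    """Inverse of :func:`energy_adjust`: absolute g/d at a given energy intake.

    Useful for rescaling recommendations stated per 10 MJ to a reference
    diet; e.g. 75 g/10 MJ corresponds to 60 g/d on an 8 MJ/d diet.
    """
    if not energy_MJ_per_day > 0:
        raise ValueError(f"energy must be > 0, got {energy_MJ_per_day}")
    return intake_g_per_basis * energy_MJ_per_day / basis_MJ


def serving_class(intake_g_d: float, serving: ServingDefinition | None = None) -> str:
    """Classify a daily intake into serving classes.

    Exact zero maps to the dedicated non-consumer class; otherwise the
    half-open bins [0,16), [16,32), [32,48), [48,inf) with the lower bound
    inclusive (16.0 g/d is one full serving).
    """
    if intake_g_d < 0:
        raise ValueError(f"intake must be >= 0, got {intake_g_d}")
    s = serving or ServingDefinition()
    labels = s.class_labels
    if intake_g_d == 0.0:
        return labels[0]
    b1, b2, b3 = s.boundaries
    if intake_g_d < b1:
        return labels[1]
    if intake_g_d < b2:
        return labels[2]
    if intake_g_d < b3:
        return labels[3]
    return labels[4]


def estimate_all(
    occasions: Sequence[DiaryOccasion],
    participants: Sequence[Participant],
    registry: Registry,
    config: PipelineConfig | None = None,
) -> list[ParticipantIntake]:
    """Score every participant: all tiers, absolute and energy-adjusted.

    Deterministic and invariant to diary row order. Participants with no
    occasions receive zero intakes; occasions whose participant has no
    demographics row are an error (they cannot be day-averaged or
    energy-adjusted).
    """
    cfg = config or PipelineConfig()
    by_participant: dict[str, list[DiaryOccasion]] = {p.participant_id: [] for p in participants}
    orphans = sorted(
        {o.participant_id for o in occasions if o.participant_id not in by_participant}
    )
    if orphans:
        raise ValueError(
            f"diary occasions reference participants without demographics: {orphans}"
        )
    for occ in occasions:
        by_participant[occ.participant_id].append(occ)
    out: list[ParticipantIntake] = []
    for p in participants:
        occs = by_participant[p.participant_id]
        g_per_day = {
            tier: daily_intake(occs, p.n_diary_days, tier, registry, cfg)
            for tier in cfg.tier_thresholds
        }
        g_per_10mj = {
            tier: energy_adjust(v, p.energy_MJ_per_day, cfg.energy_basis_MJ)
            for tier, v in g_per_day.items()
        }
        out.append(
            ParticipantIntake(
                participant_id=p.participant_id,
                wg_g_per_day=g_per_day,
                wg_g_per_10MJ=g_per_10mj,
                serving_class=serving_class(g_per_day[CutoffTier.ANY], cfg.serving),
                is_nonconsumer={t: v == 0.0 for t, v in g_per_day.items()},
            )
        )
    return out


def intakes_to_frame(intakes: Sequence[ParticipantIntake]) -> pd.DataFrame:
    """Flatten ParticipantIntake records into a tidy DataFrame (one row/person)."""
    rows = []
    for it in intakes:
        row: dict[str, object] = {"participant_id": it.participant_id}
        for tier, v in it.wg_g_per_day.items():
            row[f"wg_g_per_day_{tier.value}"] = v
        for tier, v in it.wg_g_per_10MJ.items():
            row[f"wg_g_per_10MJ_{tier.value}"] = v
        row["serving_class"] = it.serving_class
        for tier, v in it.is_nonconsumer.items():
            row[f"nonconsumer_{tier.value}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
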
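"""Diet-diary occasions, participants and composite-food splitting.

A diary records eating occasions (participant, day, food code, grams) over
3 or 4 consecutive days. Composite items such as sandwiches are split into
component food codes with user-supplied mass fractions, mirroring how survey
coders assign individual codes to home-made meals.

Food codes absent from the composition registry are retained: by
construction they contribute zero whole grain, and most foods in a real
diary are not whole-grain foods.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .composition import Registry

__all__ = [
    "DiaryOccasion",
    "Participant",
    "DiaryError",
    "load_diary",
    "load_participants",
    "load_split_map",
    "split_composites",
]

VALID_DIARY_DAYS = (3, 4)


class DiaryError(ValueError):
    """Raised for malformed diary or participant rows."""


@dataclass(frozen=True)
class DiaryOccasion:
    """One recorded consumption event."""

    participant_id: str
    day_index: int
    food_code: str
    consumed_g: float

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise DiaryError(f"day_index must be >= 1, got {self.day_index}")
        if not self.consumed_g >= 0:  # also rejects NaN
            raise DiaryError(f"consumed_g must be finite and >= 0, got {self.consumed_g}")


@dataclass(frozen=True)
class Participant:
    """Demographics, survey weight and diary metadata for one person.

    ``nssec`` is the socio-economic class (1 most advantaged … 8 never
    worked) of the household reference person, or None when missing (about
    2 % of a typical survey). ``energy_MJ_per_day`` is the mean daily energy
    intake reported in the diary, used for energy adjustment.
    """

    participant_id: str
    age_years: float
    sex: str  # "male" | "female"
    nssec: int | None
    survey_weight: float
    n_diary_days: int
    energy_MJ_per_day: float

    def __post_init__(self) -> None:
        if self.age_years < 1.5:
            raise DiaryError(f"age_years must be >= 1.5, got {self.age_years}")
        if self.sex not in ("male", "female"):
            raise DiaryError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.nssec is not None and not 1 <= self.nssec <= 8:
            raise DiaryError(f"nssec must be 1-8 or missing, got {self.nssec}")
        if not self.survey_weight > 0:
            raise DiaryError(f"survey_weight must be > 0, got {self.survey_weight}")
        if self.n_diary_days not in VALID_DIARY_DAYS:
            raise DiaryError(f"n_diary_days must be in {VALID_DIARY_DAYS}")
        if not self.energy_MJ_per_day > 0:
            raise DiaryError(f"energy_MJ_per_day must be > 0")

    @property
    def is_adult(self) -> bool:
        return self.age_years >= 18.0


def load_diary(
    path: str | Path, registry: Registry | None = None
) -> list[DiaryOccasion]:
    """Read diary occasions from CSV (participant_id, day_index, food_code, consumed_g).

    Order-preserving. If a registry is given, occasions whose food code it
    does not contain are reported with a warning but retained — such foods
    simply contribute no whole grain.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "food_code": str})
    required = {"participant_id", "day_index", "food_code", "consumed_g"}
    if not required.issubset(df.columns):
        raise DiaryError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    occasions: list[DiaryOccasion] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            occasions.append(
                DiaryOccasion(
                    participant_id=str(row.participant_id),
                    day_index=int(row.day_index),
                    food_code=str(row.food_code),
                    consumed_g=float(row.consumed_g),
                )
            )
        except DiaryError as e:
            raise DiaryError(f"{path}: row {i}: {e}") from None
    if registry is not None:
        unknown = sorted({o.food_code for o in occasions if o.food_code not in registry})
        if unknown:
            warnings.warn(
                f"{len(unknown)} food codes not in registry (treated as "
                f"non-whole-grain): {unknown[:10]}{'...' if len(unknown) > 10 else ''}",
                stacklevel=2,
            )
    return occasions


def load_participants(path: str | Path) -> list[Participant]:
    """Read the participant table from CSV.

    Columns: participant_id, age_years, sex, nssec (blank = missing),
    survey_weight, n_diary_days, energy_MJ_per_day.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    out: list[Participant] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        nssec = row.nssec
        nssec = None if pd.isna(nssec) else int(nssec)
        try:
            out.append(
                Participant(
                    participant_id=str(row.participant_id),
                    age_years=float(row.age_years),
                    sex=str(row.sex),
                    nssec=nssec,
                    survey_weight=float(row.survey_weight),
                    n_diary_days=int(row.n_diary_days),
                    energy_MJ_per_day=float(row.energy_MJ_per_day),
                )
            )
        except DiaryError as e:
            raise DiaryError(f"{path}: row {i}: {e}") from None
    return out


SplitMap = Mapping[str, Sequence[tuple[str, float]]]


def load_split_map(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    """Load a composite-food split map from JSON or YAML.

    The file maps a composite food code to ``{component_code: fraction}``
    (or a list of ``[component_code, fraction]`` pairs); fractions are
    positive and sum to at most 1.
    """
    text = Path(path).read_text(encoding="utf-8")
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    out: dict[str, list[tuple[str, float]]] = {}
    for comp, parts in (raw or {}).items():
        pairs = list(parts.items()) if isinstance(parts, Mapping) else [tuple(p) for p in parts]
        out[comp] = [(str(c), float(f)) for c, f in pairs]
    _validate_split_map(out)
    return out


def _validate_split_map(split_map: SplitMap) -> None:
    for comp, parts in split_map.items():
        total = 0.0
        for code, frac in parts:
            if frac <= 0:
                raise DiaryError(f"split map {comp!r}: fraction must be > 0, got {frac}")
            total += frac
        if total > 1.0 + 1e-9:
            raise DiaryError(f"split map {comp!r}: fractions sum to {total:g} > 1")


def split_composites(
    occasions: Iterable[DiaryOccasion], split_map: SplitMap
) -> list[DiaryOccasion]:
    """Replace mapped composite occasions by their component occasions.

    Each component receives ``consumed_g × fraction``; unmapped occasions
    pass through unchanged. Total mass is conserved when fractions sum to 1.
    """
    _validate_split_map(split_map)
    out: list[DiaryOccasion] = []
    for occ in occasions:
        parts = split_map.get(occ.food_code)
        if parts is None:
            out.append(occ)
        else:
            for code, frac in parts:
                out.append(
                    DiaryOccasion(
                        participant_id=occ.participant_id,
                        day_index=occ.day_index,
                        food_code=code,
                        consumed_g=occ.consumed_g * frac,
                    )
                )
    return out
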
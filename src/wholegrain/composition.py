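"""Whole-grain food composition registry.

A registry row states, for one food code, how many grams of whole-grain
ingredient (dry-matter basis) are contained in 100 g of the food *as it
appears in the registry*. Cooked variants of a food (e.g. toast) may either
carry their own percentage or reference an uncooked parent record together
with a cooking weight-loss factor; in the latter case the consumed mass is
mapped back to the uncooked basis before the parent's percentage is applied.

Whole-grain percentages for recipe foods are derived from their grain
ingredients by removing the ingredient's water fraction (dry-matter
conversion) and any processing loss.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "GrainType",
    "FoodGroup",
    "FoodCompositionRecord",
    "RecipeIngredient",
    "Registry",
    "RegistryError",
    "derive_wg_percent",
    "cooked_equivalent_mass",
    "load_registry",
    "save_registry",
    "default_registry",
]


class GrainType(str, Enum):
    """Closed enumeration of the cereal grains counted as whole grain."""

    WHEAT = "wheat"
    OATS = "oats"
    MAIZE = "maize"
    RICE = "rice"
    RYE = "rye"
    BARLEY = "barley"
    QUINOA = "quinoa"
    MILLET = "millet"


class FoodGroup(str, Enum):
    """The nine commodity groups whole-grain foods are sorted into."""

    BAKES = "bakes"
    BREAD = "bread"
    PASTA = "pasta"
    PORRIDGE = "porridge"
    RTEC = "RTEC"
    RICE = "rice"
    SAVOURY_SNACKS = "savoury_snacks"
    SWEET_SNACKS = "sweet_snacks"
    OTHER_CEREALS = "other_cereals"


class RegistryError(ValueError):
    """Raised for malformed registry content (row number included if known)."""


@dataclass(frozen=True)
class RecipeIngredient:
    """One grain ingredient of a recipe food.

    Parameters
    ----------
    grain
        Which grain the ingredient is.
    fresh_mass_per_100g_food
        Grams of the fresh (as-purchased) ingredient per 100 g finished food.
    water_percent
        Water content of the fresh ingredient, percent by mass. Removing it
        converts the ingredient to a dry-matter basis.
    processing_loss_percent
        Percent of ingredient mass lost during processing of the food.
    """

    grain: GrainType
    fresh_mass_per_100g_food: float
    water_percent: float = 0.0
    processing_loss_percent: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fresh_mass_per_100g_food <= 100.0:
            raise RegistryError(
                f"fresh_mass_per_100g_food must be in [0, 100], "
                f"got {self.fresh_mass_per_100g_food}"
            )
        for name in ("water_percent", "processing_loss_percent"):
            v = getattr(self, name)
            if not 0.0 <= v < 100.0:
                raise RegistryError(f"{name} must be in [0, 100), got {v}")


@dataclass
class FoodCompositionRecord:
    """Whole-grain composition of one food code.

    ``grain_content`` maps each grain to grams of whole grain (dry matter)
    per 100 g of the food as consumed in its registry form. A cooked item
    may instead reference its uncooked parent via ``cooked_form_of`` plus a
    ``cooking_loss_percent``; its own ``grain_content`` is then empty and
    content is resolved through the parent.
    """

    food_code: str
    description: str
    food_group: FoodGroup
    grain_content: dict[GrainType, float] = field(default_factory=dict)
    cooking_loss_percent: float = 0.0
    cooked_form_of: str | None = None

    def __post_init__(self) -> None:
        for grain, grams in self.grain_content.items():
            if not isinstance(grain, GrainType):
                raise RegistryError(f"unknown grain type: {grain!r}")
            if not 0.0 <= grams <= 100.0:
                raise RegistryError(
                    f"{self.food_code}: grain content for {grain.value} "
                    f"must be in [0, 100], got {grams}"
                )
        total = sum(self.grain_content.values())
        if total > 100.0 + 1e-9:
            raise RegistryError(
                f"{self.food_code}: total whole-grain content {total:g} g/100 g "
                f"exceeds 100"
            )
        if not 0.0 <= self.cooking_loss_percent < 100.0:
            raise RegistryError(
                f"{self.food_code}: cooking_loss_percent must be in [0, 100), "
                f"got {self.cooking_loss_percent}"
            )

    @property
    def total_wg_percent(self) -> float:
        """Total whole-grain grams per 100 g in registry form (sum over grains)."""
        return float(sum(self.grain_content.values()))


def derive_wg_percent(
    ingredients: Iterable[RecipeIngredient],
) -> dict[GrainType, float]:
    """Derive a food's whole-grain content from its grain ingredients.

    Each ingredient contributes
    ``fresh_mass × (1 − water/100) × (1 − processing_loss/100)`` grams of
    whole grain (dry-matter basis) per 100 g of food; contributions from the
    same grain are summed.

    Returns
    -------
    dict mapping GrainType to g whole grain (DM) per 100 g food. Empty for
    an empty ingredient list.

    Examples
    --------
    Wholemeal bread made with 70 g wholemeal flour (14 % water) per 100 g:

    >>> out = derive_wg_percent([RecipeIngredient(GrainType.WHEAT, 70, 14)])
    >>> round(out[GrainType.WHEAT], 1)
    60.2
    """
    out: dict[GrainType, float] = {}
    total = 0.0
    for ing in ingredients:
        dm = (
            ing.fresh_mass_per_100g_food
            * (1.0 - ing.water_percent / 100.0)
            * (1.0 - ing.processing_loss_percent / 100.0)
        )
        out[ing.grain] = out.get(ing.grain, 0.0) + dm
        total += dm
    if total > 100.0 + 1e-9:
        raise RegistryError(
            f"derived whole-grain content {total:g} g/100 g exceeds 100"
        )
    return out


def cooked_equivalent_mass(consumed_g: float, cooking_loss_percent: float) -> float:
    """Map a cooked portion back to the mass basis of its uncooked record.

    A food losing ``cooking_loss_percent`` of its mass on cooking means
    ``consumed_g`` of the cooked food came from
    ``consumed_g / (1 − loss/100)`` of the uncooked food, which is the basis
    on which the registry percentage is stated.

    >>> cooked_equivalent_mass(85.4, 14.6)
    100.0
    """
    if consumed_g < 0:
        raise RegistryError(f"consumed_g must be >= 0, got {consumed_g}")
    if not 0.0 <= cooking_loss_percent < 100.0:
        raise RegistryError(
            f"cooking_loss_percent must be in [0, 100), got {cooking_loss_percent}"
        )
    return consumed_g / (1.0 - cooking_loss_percent / 100.0)


class Registry:
    """Lookup table of :class:`FoodCompositionRecord` keyed by food code.

    Resolves cooked items through their uncooked parents, so callers can ask
    for whole-grain grams of a consumed portion, or for the food's effective
    whole-grain percentage per 100 g as eaten, without caring which form the
    registry stores.
    """

    def __init__(self, records: Iterable[FoodCompositionRecord]):
        self._records: dict[str, FoodCompositionRecord] = {}
        for rec in records:
            if rec.food_code in self._records:
                raise RegistryError(f"duplicate food_code {rec.food_code!r}")
            self._records[rec.food_code] = rec
        for rec in self._records.values():
            if rec.cooked_form_of is not None:
                parent = self._records.get(rec.cooked_form_of)
                if parent is None:
                    raise RegistryError(
                        f"{rec.food_code}: cooked_form_of references unknown "
                        f"food_code {rec.cooked_form_of!r}"
                    )
                if parent.cooked_form_of is not None:
                    raise RegistryError(
                        f"{rec.food_code}: cooked_form_of chains are not allowed"
                    )

    def __contains__(self, food_code: str) -> bool:
        return food_code in self._records

    def __iter__(self) -> Iterator[FoodCompositionRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def record(self, food_code: str) -> FoodCompositionRecord:
        return self._records[food_code]

    def _basis(self, rec: FoodCompositionRecord) -> FoodCompositionRecord:
        return (
            self._records[rec.cooked_form_of]
            if rec.cooked_form_of is not None
            else rec
        )

    def grain_grams(self, food_code: str, consumed_g: float) -> dict[GrainType, float]:
        """Grams of whole grain per grain type in ``consumed_g`` of the food.

        Unknown food codes contribute zero whole grain (empty map): by
        construction, foods absent from the registry are non-whole-grain.
        """
        rec = self._records.get(food_code)
        if rec is None:
            return {}
        basis = self._basis(rec)
        mass = (
            cooked_equivalent_mass(consumed_g, rec.cooking_loss_percent)
            if rec.cooked_form_of is not None
            else consumed_g
        )
        return {g: mass * p / 100.0 for g, p in basis.grain_content.items() if p > 0}

    def effective_wg_percent(self, food_code: str) -> float:
        """Whole-grain grams per 100 g of the food *as eaten*.

        For cooked items this exceeds the parent's registry percentage by the
        factor 1/(1 − loss/100), since cooking concentrates the grain. Cut-off
        tiers are applied to this figure. Unknown codes return 0.
        """
        rec = self._records.get(food_code)
        if rec is None:
            return 0.0
        basis = self._basis(rec)
        pct = basis.total_wg_percent
        if rec.cooked_form_of is not None:
            pct /= 1.0 - rec.cooking_loss_percent / 100.0
        return pct

    def food_group(self, food_code: str) -> FoodGroup | None:
        rec = self._records.get(food_code)
        return rec.food_group if rec is not None else None


_GRAIN_COLUMNS = [g.value for g in GrainType]
_HEADER = (
    ["food_code", "description", "food_group"]
    + _GRAIN_COLUMNS
    + ["cooking_loss_percent", "cooked_form_of"]
)


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def load_registry(path: str | Path) -> Registry:
    """Load a registry from delimited text (comma, tab or semicolon).

    Raises :class:`RegistryError` naming the 1-based data row for malformed
    rows, unknown food groups, out-of-range contents and duplicate codes.
    """
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text.splitlines()[0] if text else "")
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None:
        raise RegistryError(f"{path}: empty registry file")
    missing = [c for c in _HEADER[:3] if c not in reader.fieldnames]
    if missing:
        raise RegistryError(f"{path}: missing required columns {missing}")
    records: list[FoodCompositionRecord] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(reader, start=1):
        try:
            code = (row["food_code"] or "").strip()
            if not code:
                raise RegistryError("empty food_code")
            try:
                group = FoodGroup(row["food_group"].strip())
            except ValueError:
                raise RegistryError(
                    f"unknown food_group {row['food_group']!r}"
                ) from None
            grain_content: dict[GrainType, float] = {}
            for col in _GRAIN_COLUMNS:
                raw = (row.get(col) or "").strip()
                if raw:
                    v = float(raw)
                    if v != 0.0:
                        grain_content[GrainType(col)] = v
            loss_raw = (row.get("cooking_loss_percent") or "").strip()
            parent_raw = (row.get("cooked_form_of") or "").strip()
            rec = FoodCompositionRecord(
                food_code=code,
                description=(row.get("description") or "").strip(),
                food_group=group,
                grain_content=grain_content,
                cooking_loss_percent=float(loss_raw) if loss_raw else 0.0,
                cooked_form_of=parent_raw or None,
            )
        except RegistryError as e:
            raise RegistryError(f"{path}: row {i}: {e}") from None
        except (KeyError, ValueError) as e:
            raise RegistryError(f"{path}: row {i}: malformed row ({e})") from None
        if code in seen:
            raise RegistryError(
                f"{path}: duplicate food_code {code!r} at rows {seen[code]} and {i}"
            )
        seen[code] = i
        records.append(rec)
    return Registry(records)


def save_registry(
    records: Iterable[FoodCompositionRecord] | Registry,
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write records to delimited text; round-trips losslessly with load."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_HEADER)
        for rec in records:
            writer.writerow(
                [rec.food_code, rec.description, rec.food_group.value]
                + [repr(rec.grain_content.get(GrainType(c), 0.0)) for c in _GRAIN_COLUMNS]
                + [repr(rec.cooking_loss_percent), rec.cooked_form_of or ""]
            )


# Reference water contents (percent by mass) used by the shipped registry.
WHEAT_WATER_PERCENT = 14.0
OAT_WATER_PERCENT = 8.9
TOAST_COOKING_LOSS_PERCENT = 14.6


def default_registry() -> Registry:
    """A small illustrative registry spanning all nine food groups.

    Recipe foods derive their percentage from grain ingredients with the
    reference water contents above (wholemeal wheat 14 %, whole oat 8.9 %);
    toast references its bread parent with a 14.6 % cooking weight loss.
    Percentages are illustrative of typical UK products, not a brand table.
    """
    W, O = GrainType.WHEAT, GrainType.OATS

    def wg(*ings: RecipeIngredient) -> dict[GrainType, float]:
        return derive_wg_percent(ings)

    records = [
        FoodCompositionRecord(
            "BRD001", "Wholemeal bread", FoodGroup.BREAD,
            wg(RecipeIngredient(W, 70.0, WHEAT_WATER_PERCENT)),
        ),
        FoodCompositionRecord(
            "BRD002", "Wholemeal bread, toasted", FoodGroup.BREAD,
            cooking_loss_percent=TOAST_COOKING_LOSS_PERCENT,
            cooked_form_of="BRD001",
        ),
        FoodCompositionRecord(
            "BRD003", "Granary-style loaf", FoodGroup.BREAD,
            wg(RecipeIngredient(W, 35.0, WHEAT_WATER_PERCENT)),
        ),
        FoodCompositionRecord(
            "RTE001", "Wholewheat biscuit cereal", FoodGroup.RTEC,
            wg(RecipeIngredient(W, 97.0, WHEAT_WATER_PERCENT)),
        ),
        FoodCompositionRecord(
            "RTE002", "Multigrain flakes", FoodGroup.RTEC,
            wg(
                RecipeIngredient(W, 40.0, WHEAT_WATER_PERCENT),
                RecipeIngredient(GrainType.MAIZE, 15.0, 12.0),
                RecipeIngredient(GrainType.RICE, 10.0, 12.9),
            ),
        ),
        FoodCompositionRecord(
            "POR001", "Porridge oats, raw", FoodGroup.PORRIDGE,
            wg(RecipeIngredient(O, 100.0, OAT_WATER_PERCENT)),
        ),
        FoodCompositionRecord(
            "POR002", "Porridge, made up with milk", FoodGroup.PORRIDGE,
            wg(RecipeIngredient(O, 16.0, OAT_WATER_PERCENT)),
        ),
        FoodCompositionRecord(
            "RIC001", "Brown rice, boiled", FoodGroup.RICE,
            {GrainType.RICE: 30.0},
        ),
        FoodCompositionRecord(
            "PAS001", "Wholewheat pasta, boiled", FoodGroup.PASTA,
            {GrainType.WHEAT: 28.0},
        ),
        FoodCompositionRecord(
            "SAV001", "Rye crispbread", FoodGroup.SAVOURY_SNACKS,
            wg(RecipeIngredient(GrainType.RYE, 90.0, 13.0)),
        ),
        FoodCompositionRecord(
            "SAV002", "Tortilla chips, wholegrain maize", FoodGroup.SAVOURY_SNACKS,
            wg(RecipeIngredient(GrainType.MAIZE, 60.0, 12.0)),
        ),
        FoodCompositionRecord(
            "SWT001", "Oat cereal bar", FoodGroup.SWEET_SNACKS,
            wg(RecipeIngredient(O, 30.0, OAT_WATER_PERCENT)),
        ),
        FoodCompositionRecord(
            "SWT002", "Digestive-style wholemeal biscuit", FoodGroup.SWEET_SNACKS,
            wg(RecipeIngredient(W, 20.0, WHEAT_WATER_PERCENT)),
        ),
        FoodCompositionRecord(
            "BAK001", "Wholemeal scone", FoodGroup.BAKES,
            wg(RecipeIngredient(W, 30.0, WHEAT_WATER_PERCENT)),
        ),
        FoodCompositionRecord(
            "OTH001", "Pearl-free whole barley, boiled", FoodGroup.OTHER_CEREALS,
            {GrainType.BARLEY: 30.0},
        ),
        FoodCompositionRecord(
            "OTH002", "Quinoa, boiled", FoodGroup.OTHER_CEREALS,
            {GrainType.QUINOA: 28.0},
        ),
        FoodCompositionRecord(
            "OTH003", "Millet porridge flakes", FoodGroup.OTHER_CEREALS,
            wg(RecipeIngredient(GrainType.MILLET, 50.0, 11.0)),
        ),
        # A low-content food below the 10 % tier: keeps the tiers distinct.
        FoodCompositionRecord(
            "SWT003", "Yoghurt with wholegrain topping", FoodGroup.SWEET_SNACKS,
            wg(RecipeIngredient(O, 6.0, OAT_WATER_PERCENT)),
        ),
    ]
    return Registry(records)
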
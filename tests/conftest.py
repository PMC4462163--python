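import pytest

from wholegrain import (
    DiaryOccasion,
    FoodCompositionRecord,
    FoodGroup,
    GrainType,
    Participant,
    Registry,
)


@pytest.fixture(scope="session")
def small_registry() -> Registry:
    """Hand-sized registry exercising every resolution rule.

    F_BREAD is a >=51 % food; F_TOAST its cooked form (14.6 % loss, so the
    effective as-eaten percentage is 60/0.854 = 70.26 %); F_CEREAL sits in
    the 10-51 % band; F_TOPPING below 10 %.
    """
    return Registry(
        [
            FoodCompositionRecord(
                "F_BREAD", "wholemeal bread", FoodGroup.BREAD,
                {GrainType.WHEAT: 60.0},
            ),
            FoodCompositionRecord(
                "F_TOAST", "wholemeal toast", FoodGroup.BREAD,
                cooking_loss_percent=14.6, cooked_form_of="F_BREAD",
            ),
            FoodCompositionRecord(
                "F_CEREAL", "mixed cereal", FoodGroup.RTEC,
                {GrainType.WHEAT: 20.0, GrainType.OATS: 20.0},
            ),
            FoodCompositionRecord(
                "F_TOPPING", "yoghurt topping", FoodGroup.SWEET_SNACKS,
                {GrainType.OATS: 6.0},
            ),
        ]
    )


@pytest.fixture(scope="session")
def three_person_fixture(small_registry):
    """Three participants with spreadsheet-checked expected intakes.

    A eats 100 g bread (60 g WG), 85.4 g toast (100 g bread-equivalent ->
    60 g WG) and 50 g topping (3 g WG, 6 % food) over 4 diary days at
    8 MJ/d. B eats two 60 g portions of the 40 % cereal (24 g WG each) and
    200 g of an unknown food over 3 days at 10 MJ/d. C records nothing.
    """
    participants = [
        Participant("A", 40.0, "female", 2, 1.5, 4, 8.0),
        Participant("B", 12.0, "male", 5, 1.0, 3, 10.0),
        Participant("C", 70.0, "male", None, 2.0, 4, 6.0),
    ]
    occasions = [
        DiaryOccasion("A", 1, "F_BREAD", 100.0),
        DiaryOccasion("A", 2, "F_TOAST", 85.4),
        DiaryOccasion("A", 3, "F_TOPPING", 50.0),
        DiaryOccasion("B", 1, "F_CEREAL", 60.0),
        DiaryOccasion("B", 2, "F_CEREAL", 60.0),
        DiaryOccasion("B", 2, "F_UNKNOWN", 200.0),
    ]
    expected = {
        # tier -> per person g/d
        "any": {"A": 123.0 / 4, "B": 48.0 / 3, "C": 0.0},
        "ge10": {"A": 120.0 / 4, "B": 48.0 / 3, "C": 0.0},
        "ge51": {"A": 120.0 / 4, "B": 0.0, "C": 0.0},
        "energy_any": {"A": (123.0 / 4) * 10 / 8, "B": 16.0, "C": 0.0},
        "serving_class": {"A": "16to<32", "B": "16to<32", "C": "0"},
    }
    return participants, occasions, expected
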
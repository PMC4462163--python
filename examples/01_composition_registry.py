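"""Deriving and storing whole-grain percentages.

Builds a registry record from recipe ingredients, shows how cooking-loss
factors map cooked portions back to the registry basis, and round-trips
the shipped illustrative registry through CSV.
"""

from wholegrain import (
    GrainType,
    RecipeIngredient,
    cooked_equivalent_mass,
    default_registry,
    derive_wg_percent,
)

# Wholemeal bread: 70 g wholemeal flour per 100 g bread. Wholemeal wheat
# holds 14 % water, so only the dry matter counts as whole grain.
bread = derive_wg_percent([RecipeIngredient(GrainType.WHEAT, 70.0, water_percent=14.0)])
print(f"wholemeal bread: {bread[GrainType.WHEAT]:.1f} g whole grain (DM) per 100 g")
# -> 60.2 g/100 g: the flour minus its water fraction.

# A muesli with two grains, one of which loses 5 % in processing.
muesli = derive_wg_percent(
    [
        RecipeIngredient(GrainType.OATS, 50.0, water_percent=8.9),
        RecipeIngredient(GrainType.WHEAT, 20.0, water_percent=14.0, processing_loss_percent=5.0),
    ]
)
for grain, grams in muesli.items():
    print(f"muesli {grain.value}: {grams:.2f} g/100 g")

# Toast loses 14.6 % of its mass in the toaster, so 85.4 g of toast is the
# whole-grain equivalent of 100 g of the bread it was made from.
print(f"85.4 g toast = {cooked_equivalent_mass(85.4, 14.6):.1f} g bread-equivalent")

# The shipped registry spans all nine food groups and eight grain types.
registry = default_registry()
print(f"\ndefault registry: {len(registry)} foods")
for rec in registry:
    basis = f" (cooked form of {rec.cooked_form_of})" if rec.cooked_form_of else ""
    print(f"  {rec.food_code}  {rec.total_wg_percent:5.1f} g/100 g  {rec.description}{basis}")
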
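"""Build the frequency-weighted tree-nut composite and its almond-only
variant, and show what a median day of snack energy weighs in nuts."""
from snacksub import (build_composite, composite_mass_for_energy,
                      load_nut_items)

items = load_nut_items()
tree = build_composite(items, "tree_nut")
almond = build_composite(items, "almond_only")

print("Tree-nut composite weights (share of consumption events):")
for item, w in sorted(tree.weights.items(), key=lambda kv: -kv[1]):
    print(f"  {item:32s} {w:.3f}")

print("\nPer-100-kcal profile highlights (tree nut vs almond only):")
for col in ("total_fat_g", "sfa_g", "mufa_g", "pufa_g", "ala_mg",
            "fiber_g", "magnesium_mg", "sodium_mg"):
    print(f"  {col:14s} {tree.per_100kcal[col]:8.2f} {almond.per_100kcal[col]:8.2f}")

g = composite_mass_for_energy(tree, 293.0)
print(f"\n293 kcal (a median day of snack energy) = {g:.0f} g of the blend")
print("The ALA column is why an almond-only substitution loses the plant")
print("omega-3 gain: walnuts carry ~1,400 mg ALA per 100 kcal, almonds ~0.5.")
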
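"""Apply the two snack-replacement rules to a synthetic population and
inspect what gets replaced and what is exempt."""
from snacksub import (GeneratorConfig, build_composite, generate_dataset,
                      load_nut_items, model1, model2, run_models)

persons, foods, _ = generate_dataset(GeneratorConfig(n_persons=400, seed=7))
comp = build_composite(load_nut_items())
out = run_models(foods, persons, {"model1": model1(comp),
                                  "model2": model2(comp)})

for name, res in out.items():
    audit = res["audit"]
    replaced = audit.loc[audit["eligible"], "energy_kcal"].sum()
    total_snack = audit.loc[audit["reason"] != "meal", "energy_kcal"].sum()
    print(f"{name}: replaced {replaced:,.0f} of {total_snack:,.0f} "
          "snack-occasion kcal")
    print("  ineligible reasons:",
          audit.loc[~audit["eligible"] & (audit['reason'] != 'meal'),
                    "reason"].value_counts().to_dict())

print("\nMean replaced snack energy (kcal/d) by age group, model 1:")
print(out["model1"]["replaced_by_age"].round(0).to_string())
print("Model 2 replaces less because whole fruit, non-starchy vegetables")
print("and majority-whole-grain snacks (e.g. popcorn) keep their place.")
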
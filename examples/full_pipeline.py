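"""Run the complete analysis on a synthetic population and print the
headline comparison tables."""
import warnings

from snacksub import GeneratorConfig, RunConfig, run_pipeline

cfg = RunConfig(generator=GeneratorConfig(n_persons=600, seed=1),
                seed=1, by_age_group=False)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    bundle = run_pipeline(cfg)

means = bundle["means"]
sel = means[(means["group"] == "all")
            & (means["dataset"] == "model1_tree_nut")]
print("Percent change vs observed diets (model 1, tree-nut composite):")
for _, row in sel.iterrows():
    print(f"  {row['outcome']:22s} {row['pct_change']:+7.1f}% "
          f"{row['stars']:3s} {row['effect_class']}")

print("\nHEI-2010 totals (0-100; higher = closer to dietary guidance):")
hei_all = bundle["hei"][bundle["hei"]["group"] == "all"]
print(hei_all[["dataset", "total"]].round(1).to_string(index=False))

print("\nThreshold attainment from the usual-intake model:")
print(bundle["thresholds"][["dataset", "nutrient", "pct_below", "pct_above"]]
      .round(1).to_string(index=False))
print("\nReplacing sugar/solid-fat-rich snacks with nuts cuts empty")
print("calories and sodium, raises unsaturated fats, fiber and magnesium,")
print("and lifts the overall diet-quality score.")
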
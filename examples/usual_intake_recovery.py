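"""Fit the usual-intake measurement-error model to simulated recalls with
known truth, and compare the recovered distribution to the analytic one."""
from snacksub import (NutrientTruth, fit_amount_model, simulate_intakes,
                      truth_summary, usual_distribution)

# sodium-like truth on the Box-Cox (lambda=0.4) scale: usual mean ~3,500
# mg/d with realistic between- and within-person spread
truth = NutrientTruth("sodium_mg", lam=0.4, mu=62.8, sigma_u=8.0,
                      sigma_e=9.0, beta_weekend=1.5, beta_sequence=-1.0)
target = truth_summary({"sodium_mg": truth},
                       thresholds_below={"sodium_mg": 2300.0}).iloc[0]

recalls = simulate_intakes(truth, n_persons=2000, seed=42, weight_sigma=0.3)
model = fit_amount_model(recalls)
dist = usual_distribution(model, seed=0, thresholds_below=(2300.0,))

print(f"selected lambda: {model.lam:.2f} (truth 0.40)")
print(f"usual mean:  est {dist.mean:7.0f}  truth {target['usual_mean']:7.0f}")
print(f"usual SD:    est {dist.sd:7.0f}  truth {target['usual_sd']:7.0f}")
print(f"% < 2300 mg/d: est {dist.pct_below[2300.0]:5.1f}  "
      f"truth {target['pct_below']:5.1f}")
print("The fitted SD is far below the day-to-day SD of the recalls: the")
print("model strips within-person noise to recover the usual-intake spread.")
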
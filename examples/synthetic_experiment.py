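"""Generate a synthetic 5-placenta perfusion experiment and analyze it.

Runs the full loop: simulate noisy perfusion datasets with known ground
truth, summarize them, test the flow effects by two-way ANOVA, and recover
the generating rate parameters by refitting.
"""

import placentaflux as pf

truth = pf.TransporterParams()
variant = pf.ModelVariant.transport_metabolism()

ds = pf.generate_dataset(truth, variant, n_placentas=5, noise_cv=0.1, seed=1)
print(f"cotyledon masses (g): {[f'{m:.1f}' for m in ds.masses]}")

summary = pf.dataset_summary(ds)
summary[["f_m", "f_f"]] = summary[["f_m", "f_f"]] * 1e3
summary[["uptake_mean", "uptake_se", "transfer_mean", "transfer_se"]] *= 1e12
print("\nper-condition means +- SE (pmol/min):")
print(summary.to_string(index=False, float_format=lambda x: f"{x:8.3f}"))

for response in ("uptake", "transfer"):
    table = pf.flow_anova(ds, response)
    print(f"\ntwo-way ANOVA on {response}:")
    print(table[["F", "PR(>F)"]].to_string(float_format=lambda x: f"{x:9.4f}"))

print("\nUptake shows a clear maternal-flow effect and no fetal effect. "
      "Transfer shows\nmaternal and fetal effects: the model's BM exchanger "
      "re-captures fetal tracer and\nintracellular tracer keeps "
      "equilibrating, unlike the flat transfer seen on the bench.")

fit = pf.recover_rates(ds)
print("\nparameter recovery from the noisy dataset:")
for name, tv, fv in [("v_ex_mvm", truth.v_ex_mvm, fit.v_ex_mvm),
                     ("v_bm", truth.v_fa_bm, fit.v_fa_bm),
                     ("k_metab", truth.k_metab, fit.k_metab)]:
    print(f"  {name:9s} truth {tv:.3e}  recovered {fv:.3e}  "
          f"({100 * abs(fv / tv - 1):.1f}% off)")
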
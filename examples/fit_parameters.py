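"""Calibrate the maximal rates and metabolic clearance to uptake/transfer
targets, and fit the diffusive permeability.

Demonstrates the round trip: generate targets from a known parameter set,
refit, and compare.
"""

import dataclasses

import placentaflux as pf

geometry = pf.CompartmentGeometry()
variant = pf.ModelVariant.transport_metabolism()

truth = dataclasses.replace(pf.TransporterParams().with_bm_vmax(1.2e-7),
                            v_ex_mvm=2.2e-6, k_metab=1.0e-4)
grid = pf.predict_grid(truth, geometry, variant).sort_values(["f_m", "f_f"])
targets = pf.FitTargets(uptake=grid["uptake"].to_numpy(),
                        transfer=grid["transfer"].to_numpy())
fitted = pf.fit_rates(targets)

print("rate fitting round trip (per-condition targets):")
for name, tv, fv in [("v_ex_mvm", truth.v_ex_mvm, fitted.v_ex_mvm),
                     ("v_bm", truth.v_fa_bm, fitted.v_fa_bm),
                     ("k_metab", truth.k_metab, fitted.k_metab)]:
    print(f"  {name:9s} truth {tv:.3e}  fitted {fv:.3e}  "
          f"({100 * abs(fv / tv - 1):.2f}% off)")

v_dif_truth = 1.5e-3
dif = dataclasses.replace(pf.TransporterParams(), v_dif=v_dif_truth)
target = pf.predict_grid(dif, geometry,
                         pf.ModelVariant.diffusion())["uptake"].mean()
v_dif = pf.fit_vdif(target)
print(f"\ndiffusive permeability round trip: truth {v_dif_truth:.3e}, "
      f"fitted {v_dif:.3e} l/min")

try:
    pf.fit_vdif(2.2e-11)
except pf.FitError as exc:
    print(f"\nfitting diffusion to the observed uptake fails as expected:\n"
          f"  {exc}")
    print("diffusive transfer is flow-limited and cannot reach the uptake "
          "the carriers achieve.")
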
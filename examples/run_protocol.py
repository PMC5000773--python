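"""Simulate the stepwise dual-perfusion protocol with the default model.

A 42-g cotyledon is perfused with 2.7 nmol/l [14C]phenylalanine on the
maternal side through a 30-min baseline and nine 20-min flow combinations
(maternal 10/14/18 ml/min x fetal 3/6/9 ml/min), then a 15-min tracer-free
wash.  Prints the per-condition uptake and transfer and the protocol totals.
"""

import placentaflux as pf

params = pf.TransporterParams()
geometry = pf.CompartmentGeometry()          # 42 g at 1 ml/g
pools = pf.SubstratePools.tracer()           # substrate-free perfusates
variant = pf.ModelVariant.transport_metabolism()
protocol = pf.build_protocol(include_wash=True)

traj = pf.simulate(protocol, params, pools, geometry, variant)
grid = pf.predict_grid(params, geometry, variant)

print("Per-condition uptake and transfer (pmol/min), quasi-steady samples:")
show = grid[["f_m", "f_f", "uptake", "transfer"]].copy()
show[["f_m", "f_f"]] *= 1e3        # -> ml/min
show[["uptake", "transfer"]] *= 1e12
print(show.to_string(index=False, float_format=lambda x: f"{x:8.3f}"))

uptake_nmol = (traj.in_m[-1] - traj.out_m[-1]) * 1e9
transfer_nmol = traj.out_f[-1] * 1e9
print(f"\nCumulative uptake over the protocol: {uptake_nmol:.2f} nmol")
print(f"Cumulative transfer to the fetal circuit: {transfer_nmol:.2f} nmol "
      f"({100 * transfer_nmol / uptake_nmol:.1f}% of uptake)")
print(f"Tracer metabolized into protein: {traj.protein[-1] * 1e9:.2f} nmol")
print(f"Mass-balance residual: {traj.mass_balance_residual(geometry):.1e}")
print("\nUptake rises with maternal flow while transfer stays an order of "
      "magnitude lower:\nmost extracted tracer is retained and metabolized, "
      "not passed on to the fetal circuit.")
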
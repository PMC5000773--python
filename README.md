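# placentaflux

Compartmental kinetic modelling of [¹⁴C]phenylalanine transfer across the
isolated, dually perfused human placental cotyledon.

Amino acids reach the fetus by crossing two membranes of the placental
syncytiotrophoblast: an exchanger (antiporter) on the maternal-facing
microvillous membrane (MVM) and exchangers plus facilitated transporters
(uniporters) on the fetal-facing basal membrane (BM). In ex vivo perfusion
experiments, phenylalanine uptake from the maternal circulation rises with
maternal flow, yet transfer to the fetal circulation stays low and flat —
most of the extracted tracer is retained and incorporated into placental
protein. `placentaflux` provides the three-compartment carrier-kinetic
model used to interpret such experiments, for researchers in placental
physiology and perfusion modelling.

## The model

Three well-mixed compartments — maternal intervillous space (m),
syncytiotrophoblast (s), fetal capillary (f) — with volumes vᵢ carved out
of a 42-g cotyledon (1 ml/g; fractions 0.25 / 0.15 / 0.05). Free tracer
concentrations [A]ⁱ evolve by

    vₘ d[A]ᵐ/dt = J_flow,m − J_ex(m→s) − J_dif(m→f)
    vₛ d[A]ˢ/dt = J_ex(m→s) − J_ex(s→f) − J_fa(s→f) − J_metab
    v_f d[A]f/dt = J_flow,f + J_ex(s→f) + J_fa(s→f) + J_dif(m→f)

with carrier flux laws (all in mol/min)

    J_ex(I→II)  = V_ex ([A]ᴵ[R]ᴵᴵ − [A]ᴵᴵ[R]ᴵ) / (K_ex([Tot]ᴵ+[Tot]ᴵᴵ)/2 + [Tot]ᴵ[Tot]ᴵᴵ)
    J_fa(I→II)  = V_fa ([A]ᴵ/(K_fa+[Tot]ᴵ) − [A]ᴵᴵ/(K_fa+[Tot]ᴵᴵ))
    J_flow,i    = Fᵢ([A]ᵢₙⁱ − [A]ⁱ)        J_metab = k_metab [A]ˢ
    J_dif(m→f)  = V_dif([A]ᵐ − [A]f)

where [R] sums the competing exchanger substrates (excluding the tracked
substrate) and [Tot] the total substrate load of a carrier. The exchanger
is trans-stimulated: tracer influx requires counter-substrate on the far
side, supplied by two fixed generic intracellular amino-acid pools
(3,132 µmol/l of facilitated+exchange substrates, 4,491 µmol/l of
exchange-only substrates). K_ex = 200 µmol/l, K_fa = 1,000 µmol/l;
maximal rates and the first-order metabolic clearance k_metab are
calibrated so the simulated experiment reproduces the reference perfusion
measurements (≈4.6 nmol uptake per protocol, ≈15 % transferred at steady
state, ≈163 nmol/l intracellular free tracer). Creatinine (1.8 mmol/l) is
co-simulated as a pure paracellular-diffusion marker.

The simulated experiment follows the stepwise protocol: 30-min baseline at
maternal/fetal flows of 14/6 ml/min, then maternal blocks of 10, 14, 18
ml/min (60 min each), each ramping fetal flow through 3, 6, 9 ml/min
(20 min each), with venous sampling at 5/10/15/18 min per block and an
optional 15-min tracer-free wash. Uptake = (C_maternal,arterial −
C_maternal,venous)·F_m; transfer = C_fetal,venous·F_f.

## Worked example

```python
import placentaflux as pf

params   = pf.TransporterParams()            # calibrated defaults
geometry = pf.CompartmentGeometry()          # 42 g cotyledon
pools    = pf.SubstratePools.tracer()        # substrate-free perfusates
variant  = pf.ModelVariant.transport_metabolism()
protocol = pf.build_protocol(include_wash=True)

traj = pf.simulate(protocol, params, pools, geometry, variant)
print((traj.in_m[-1] - traj.out_m[-1]) * 1e9)   # cumulative uptake, nmol
grid = pf.predict_grid(params, geometry, variant)
print(grid[["f_m", "f_f", "uptake", "transfer"]])
```

Running `python examples/run_protocol.py` prints the 9-condition table and

```
Cumulative uptake over the protocol: 4.52 nmol
Cumulative transfer to the fetal circuit: 0.54 nmol (11.9% of uptake)
Tracer metabolized into protein: 3.17 nmol
Mass-balance residual: 1.9e-15
```

i.e. the model takes up ≈4.5 nmol of tracer over the 3.5-h protocol,
passes ≈12 % of it to the fetal circuit (rising toward the 15 %
steady-state share as the intracellular pool equilibrates), metabolizes the
rest, and conserves tracer to solver precision. Uptake climbs from 17.7 to
25.0 pmol/min as maternal flow goes 10→18 ml/min while transfer stays an
order of magnitude smaller — the experiment's central observation.

The other scripts in `examples/` each exercise one capability:
variant comparison (diffusion vs transport vs metabolism, and the collapse
of the flow dependence at physiological amino-acid levels), 5-fold
parameter sensitivity, rate fitting and the infeasibility of a diffusive
explanation of uptake, synthetic multi-placenta experiments with ANOVA and
parameter recovery, and the tracer mass-balance accounting.

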
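# Methods

## Model structure and assumptions

The perfused cotyledon is represented as three well-mixed compartments:
maternal intervillous space (m), syncytiotrophoblast (s) and fetal
capillary (f). Well-mixedness implies venous outflow concentration equals
compartment concentration, which is how sampled "venous" values are read
off a trajectory. Dynamic species are the [¹⁴C]phenylalanine tracer in all
three compartments, creatinine in the two perfused compartments, and the
cumulative protein-incorporated tracer P (a running amount, not a
concentration). Everything else — in particular the two generic
intracellular amino-acid pools — is a fixed boundary condition.

Internal units are mol, liters and minutes throughout; µmol/l, nmol and
ml/min appear only at I/O boundaries.

### Carrier kinetics

The exchanger flux law is the symmetric-carrier exchange form

J = V_ex (A₁R₂ − A₂R₁) / (K_ex(Tot₁+Tot₂)/2 + Tot₁Tot₂),

with one dissociation constant on both membrane faces. This form has the
properties a symmetric antiporter must have: antisymmetry under swapping
the faces, zero flux at exchange equilibrium (A₁R₂ = A₂R₁), and
trans-stimulation — no net tracer flux without counter-substrate on the
far side. It is a reconstruction: published renderings of this equation
are frequently garbled typographically, so the implementation follows the
algebraic form implied by the stated carrier symmetry and is pinned by
hand-computed values in the test suite. [Tot] includes the tracked
substrate itself; [R] excludes it. At tracer concentrations the
distinction is ~10⁻⁵ relative but is carried exactly.

The facilitated (uniporter) law J = V_fa(A₁/(K_fa+Tot₁) − A₂/(K_fa+Tot₂))
saturates at |J| < V_fa and shows trans-inhibition by cis substrate load.
Metabolism is linear (unsaturated) clearance k_metab·[A]ˢ into P; release
from protein is not modelled because protein half-lives far exceed the
protocol duration. Diffusion and flow are linear exchange terms.

### Model variants

Mechanisms are switched term-by-term: `diffusion` (paracellular route
only), `transport` (carriers without metabolism), `transport+metabolism`
(default), plus an optional intracellular clamp (d[A]ˢ/dt = 0) emulating
perfect homeostasis of the free intracellular pool. Creatinine always
moves by flow and diffusion regardless of the tracer's variant flags,
since it is a passive marker species. The notation of the source framework
also names an accumulative ("ac") transporter class; it enters no flux
equation and is not implemented.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| K_ex | exchanger dissociation constant | 200e-6 | mol/l |
| K_fa | facilitated-transporter dissociation constant | 1,000e-6 | mol/l |
| V_ex_mvm | MVM exchanger maximal rate | 1.9e-6 | mol/min |
| V_ex_bm = V_fa_bm | shared BM maximal rate | 9.7e-8 | mol/min |
| k_metab | metabolic clearance | 1.15e-4 | l/min |
| V_dif | effective diffusive permeability | 2.0e-3 | l/min |
| pools (s) | fa+ex / ex-only substrate pools | 3,132e-6 / 4,491e-6 | mol/l |
| pools (m, physiological) | maternal arterial pools | 615e-6 / 915e-6 | mol/l |
| tracer inflow | maternal arterial [¹⁴C]Phe | 2.7e-9 | mol/l |
| creatinine inflow | maternal arterial marker | 1.8e-3 | mol/l |
| geometry | 42 g at 1 ml/g; fractions m/s/f | 0.25/0.15/0.05 | — |

The maximal rates and clearance are not independently measurable in this
preparation; the defaults were derived analytically, once, from the
steady-state balance so that the simulated experiment reproduces the
reference perfusion aggregates. In the trace-linear regime the MVM
exchanger acts as a clearance c = V_ex_mvm·2R_s/(K_ex·Tot_s) ≈ 10⁴·V_ex_mvm,
and uptake = F_m·c/(F_m+c)·A_in; V_ex_mvm = 1.9e-6 reproduces mean uptake
≈ 2.15e-11 mol/min (≈4.5 nmol per 3.5-h protocol) and a ≈40 % uptake rise
from the slowest to the fastest maternal flow. On the BM, writing
k_f = V_fa/(K_fa+Tot_fa,s) for the forward facilitated slope and
k_b ≈ 10⁴·V_ex_bm for exchanger re-capture of fetal tracer, the
steady-state conditions (transfer = 15 % of uptake, intracellular free
tracer ≈163 nmol/l at baseline flows) pin V_bm = 9.7e-8 and
k_metab = 1.15e-4.

V_dif cannot be fitted to the observed uptake at all: the diffusion-only
model's uptake is bounded by the flow limit F_m·F_f/(F_m+F_f)·A_in
≈ 1.1e-11 mol/min, roughly half the observed value — which is precisely
the argument for carrier-mediated uptake. `fit_vdif` raises on such
targets; the default V_dif = 2e-3 l/min is a representative
sub-flow-limited permeability that also serves the creatinine marker
(which shares the parameter; no separate creatinine permeability is
published for this preparation).

The tracer inflow is 2.7 nmol/l; where sources disagree on the unit
(nmol/l vs pmol/l) the nmol/l methods value is used, and trace-linearity
makes the distinction immaterial for all flow-response patterns.

## Numerics

Each constant-flow segment is integrated with LSODA (stiff-safe) and the
solver restarts at every flow change; state is carried continuously across
the event while fluxes jump. Tolerances: rtol 1e-8, atol 1e-15 (mol/l at
tracer scale), both configurable. Cumulative inflow/outflow per circuit
are co-integrated so the conservation identity Σvᵢ[A]ⁱ + P = inflow −
outflow can be asserted along any trajectory; it holds to ≈1e-15 relative
in practice (internal fluxes cancel pairwise in exact arithmetic, so the
residual is pure integration error). Concentrations are clipped to zero
inside flux evaluations and projected to the nonnegative orthant between
segments, with a warning if the projection exceeds 100·atol.

Steady states solve the nonlinear root problem on the five concentration
variables (scaled to the dominant flow flux) with a Powell hybrid method;
the accepted residual must be < 1e-12 of that scale, and the result agrees
with long-time integration to better than 0.1 %. P is excluded — it grows
without bound whenever metabolism is active.

Rate fitting is deterministic bounded least squares on log₁₀ parameters
from a fixed multi-start grid (decade offsets around the incumbent
values), replacing irreproducible manual adjustment. With only scalar
mean uptake/transfer targets the pair (V_bm, k_metab) is identified only
through its ratio — jointly scaling both leaves steady-state transfer
unchanged — so `FitTargets` also accepts the 9-condition uptake/transfer
vectors, whose protocol-time transients break the degeneracy and make all
three rates identifiable (verified by round-trip recovery tests).
`recover_rates` additionally fits at the dataset's measured mean cotyledon
mass and rescales to the 42-g reference, because uptake is concave in
tissue mass and fitting at the reference geometry would be biased by mass
sampling.

Sensitivity analysis perturbs each kinetic parameter 5-fold in both
directions (dropping the shared-BM-Vmax constraint, which a one-parameter
perturbation necessarily violates) and reports protocol-mean uptake and
transfer as ratios to baseline.

The two-way flow ANOVA is the ordinary fixed-effects OLS procedure on
placenta-level condition means (type-II sums of squares); the
repeated-measures structure of the design is acknowledged but not
modelled. A zero-variance response returns NaN p-values rather than
spurious significance.

## Synthetic data

The generator emulates the perfusion experiment's output structure: per
placenta, a cotyledon mass drawn from N(42.0, 9.7²) g truncated above
10 g, geometry and all extensive rates (Vmax, k_metab, V_dif) scaled
proportionally to mass (constant transporter density per gram), a full
protocol simulation, and mean-one multiplicative lognormal noise on every
sampled venous concentration (default CV 0.1, as scintillation-counting
error scales with signal; no published error model exists for this
preparation). Uptake and transfer per condition use the 15- and 18-min
quasi-steady samples, as the experiment defines them.

Not emulated: incomplete intervillous mixing, perfusate recovery drift,
quenching, or the ~44 % of retained tracer the bench experiment could not
recover. Passing tests on these datasets therefore demonstrate pipeline
correctness under the model's own assumptions, not robustness to those
experimental artifacts.

## Design choices on open points

- **Sampling semantics.** "Steady-state" per sub-block is measured at the
  15- and 18-min samples; both and their mean are reported, alongside
  whole-sub-block time averages.
- **Equilibration.** All-zero initial tracer with a 30-min baseline
  segment as equilibration (configurable; protocol descriptions of this
  experiment variously give 20 or 30 min).
- **Physiological mode** sets the maternal generic pools to 615/915
  µmol/l and leaves the labelled tracer at 2.7 nmol/l; the collapse of the
  maternal-flow dependence of uptake arises from the pools (carrier
  competition), not from the tracer level.
- **Fetal generic pools** stay at zero: endogenous substrates effluxed
  across the BM are washed out by fetal flow and are not tracked.
- **Wash phase** (15 min, tracer-free) is implemented and excluded from
  uptake/transfer summaries.

## Known limitations

- Transfer in the transport+metabolism model retains a genuine fetal-flow
  dependence (steady-state ratio ≈1.2 from 3 to 9 ml/min) through BM
  exchanger re-capture of fetal tracer, plus a slow intracellular
  transient (time constant ≈47 min at default rates, so the 30-min
  baseline does not fully equilibrate the syncytiotrophoblast). Bench
  experiments show flat transfer; this residual disagreement is a
  documented property of the model class, not an implementation artifact.
  The intracellular clamp removes the transient component but not the
  re-capture component, which is structural under the shared BM Vmax.
- Carrier kinetics are symmetric by construction; asymmetric transporters
  and substrate competition beyond the two generic pools are out of scope.
- Flows are ideal (no perfusate losses), and no spatial structure of the
  intervillous space is modelled.
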
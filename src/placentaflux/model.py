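"""Three-compartment ODE right-hand side for tracer and creatinine.

State layout (see :class:`placentaflux.params.CompartmentState`):

    d a_m/dt = (J_flow^m - J_ex^{m->s} - J_dif^{m->f}) / v_m
    d a_s/dt = (J_ex^{m->s} - J_ex^{s->f} - J_fa^{s->f} - J_metab) / v_s
    d a_f/dt = (J_flow^f + J_ex^{s->f} + J_fa^{s->f} + J_dif^{m->f}) / v_f

with the exchanger on the microvillous membrane (m<->s), exchanger and
facilitated transporter on the basal membrane (s<->f), paracellular
diffusion (m<->f), flow through both circuits, and first-order metabolism in
the syncytiotrophoblast feeding a cumulative protein pool P (dP/dt =
J_metab).  Creatinine moves by flow and diffusion only.  Disabled mechanisms
are omitted term-by-term according to the :class:`ModelVariant` flags.

Summing ``v_i * dA_i/dt + dP/dt`` over compartments cancels every internal
flux pairwise, so total tracer changes only through the two flow terms —
this conservation identity is asserted along integrated trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fluxes import (
    diffusion_flux,
    exchanger_flux,
    facilitated_flux,
    flow_flux,
    metabolic_flux,
)
from .params import (
    CREATININE_INFLOW,
    TRACER_INFLOW,
    CompartmentGeometry,
    CompartmentState,
    ModelVariant,
    SubstratePools,
    TransporterParams,
)

__all__ = ["Inflows", "rhs", "tracer_fluxes"]


@dataclass(frozen=True)
class Inflows:
    """Arterial inflow concentrations (mol/l) for each circuit."""

    tracer_m: float = TRACER_INFLOW
    tracer_f: float = 0.0
    creatinine_m: float = CREATININE_INFLOW
    creatinine_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tracer_m", "tracer_f", "creatinine_m", "creatinine_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def wash(cls) -> "Inflows":
        """Tracer-free wash perfusate (creatinine also absent)."""
        return cls(tracer_m=0.0, creatinine_m=0.0)


def tracer_fluxes(
    state: CompartmentState,
    pools: SubstratePools,
    params: TransporterParams,
    f_m: float,
    f_f: float,
    inflows: Inflows,
    variant: ModelVariant,
) -> dict:
    """All instantaneous tracer fluxes (mol/min), keyed by pathway.

    The exchanger pool of each compartment is the two generic pools plus the
    tracer itself ([Tot] includes A); the counter-substrate concentration
    [R] excludes the tracer.  At tracer concentrations the distinction is
    numerically negligible but is carried exactly.
    """
    a_m, a_s, a_f = state.a_m, state.a_s, state.a_f
    if any(math.isnan(x) for x in (a_m, a_s, a_f, state.c_m, state.c_f)):
        raise ValueError("NaN in model state")

    r_m = pools.exchanger_pool("m")
    r_s = pools.exchanger_pool("s")
    r_f = pools.exchanger_pool("f")
    tot_m, tot_s, tot_f = a_m + r_m, a_s + r_s, a_f + r_f
    tot_fa_s = a_s + pools.facilitated_pool("s")
    tot_fa_f = a_f + pools.facilitated_pool("f")

    out = {
        "flow_m": flow_flux(f_m, inflows.tracer_m, a_m),
        "flow_f": flow_flux(f_f, inflows.tracer_f, a_f),
        "ex_ms": 0.0,
        "ex_sf": 0.0,
        "fa_sf": 0.0,
        "dif_mf": 0.0,
        "metab": 0.0,
    }
    if variant.transport_enabled:
        out["ex_ms"] = exchanger_flux(
            a_m, a_s, r_m, r_s, tot_m, tot_s, params.v_ex_mvm, params.k_ex
        )
        out["ex_sf"] = exchanger_flux(
            a_s, a_f, r_s, r_f, tot_s, tot_f, params.v_ex_bm, params.k_ex
        )
        out["fa_sf"] = facilitated_flux(
            a_s, a_f, tot_fa_s, tot_fa_f, params.v_fa_bm, params.k_fa
        )
    if variant.diffusion_enabled:
        out["dif_mf"] = diffusion_flux(a_m, a_f, params.v_dif)
    if variant.metabolism_enabled:
        out["metab"] = metabolic_flux(a_s, params.k_metab)
    return out


def rhs(
    state: CompartmentState,
    pools: SubstratePools,
    params: TransporterParams,
    geometry: CompartmentGeometry,
    f_m: float,
    f_f: float,
    inflows: Inflows,
    variant: ModelVariant,
) -> CompartmentState:
    """Time derivative of the dynamic state (concentrations per minute)."""
    j = tracer_fluxes(state, pools, params, f_m, f_f, inflows, variant)
    v_m, v_s, v_f = geometry.v_m, geometry.v_s, geometry.v_f

    da_m = (j["flow_m"] - j["ex_ms"] - j["dif_mf"]) / v_m
    da_s = (j["ex_ms"] - j["ex_sf"] - j["fa_sf"] - j["metab"]) / v_s
    da_f = (j["flow_f"] + j["ex_sf"] + j["fa_sf"] + j["dif_mf"]) / v_f
    if variant.clamp_intracellular:
        da_s = 0.0

    # creatinine: flow + paracellular diffusion, unconditionally
    j_dif_c = diffusion_flux(state.c_m, state.c_f, params.v_dif)
    dc_m = (flow_flux(f_m, inflows.creatinine_m, state.c_m) - j_dif_c) / v_m
    dc_f = (flow_flux(f_f, inflows.creatinine_f, state.c_f) + j_dif_c) / v_f

    deriv = CompartmentState.__new__(CompartmentState)
    deriv.a_m, deriv.a_s, deriv.a_f = da_m, da_s, da_f
    deriv.c_m, deriv.c_f = dc_m, dc_f
    deriv.protein = j["metab"]
    return deriv


# ---------------------------------------------------------------------------
# fast vector form used by the integrator
# ---------------------------------------------------------------------------
# y = [a_m, a_s, a_f, c_m, c_f, P, in_m, out_m, in_f, out_f]
#     concentrations (mol/l), then cumulative amounts (mol): protein pool and
#     tracer carried in/out by each circuit.
N_STATE = 10
IDX = {name: i for i, name in enumerate(
    ["a_m", "a_s", "a_f", "c_m", "c_f", "protein",
     "in_m", "out_m", "in_f", "out_f"])}


def make_rhs_vec(
    pools: SubstratePools,
    params: TransporterParams,
    geometry: CompartmentGeometry,
    f_m: float,
    f_f: float,
    inflows: Inflows,
    variant: ModelVariant,
):
    """Closure ``f(t, y) -> dy`` over plain floats, for scipy's solvers.

    Negative concentrations that transiently arise inside solver trial steps
    are clipped to zero before evaluating the flux laws, which keeps the
    carrier denominators well behaved; the integrator's accepted solution is
    additionally projected in the simulator.
    """
    v_m, v_s, v_f = geometry.v_m, geometry.v_s, geometry.v_f
    r_m = pools.exchanger_pool("m")
    r_s = pools.exchanger_pool("s")
    r_f = pools.exchanger_pool("f")
    p_fa_s = pools.facilitated_pool("s")
    p_fa_f = pools.facilitated_pool("f")
    k_ex, k_fa = params.k_ex, params.k_fa
    v_ex_mvm, v_ex_bm, v_fa_bm = params.v_ex_mvm, params.v_ex_bm, params.v_fa_bm
    k_metab = params.k_metab if variant.metabolism_enabled else 0.0
    v_dif_tracer = params.v_dif if variant.diffusion_enabled else 0.0
    v_dif = params.v_dif
    transport = variant.transport_enabled
    clamp = variant.clamp_intracellular
    a_in_m, a_in_f = inflows.tracer_m, inflows.tracer_f
    c_in_m, c_in_f = inflows.creatinine_m, inflows.creatinine_f

    def f(t: float, y: np.ndarray) -> np.ndarray:
        a_m = y[0] if y[0] > 0.0 else 0.0
        a_s = y[1] if y[1] > 0.0 else 0.0
        a_f = y[2] if y[2] > 0.0 else 0.0
        c_m = y[3] if y[3] > 0.0 else 0.0
        c_f = y[4] if y[4] > 0.0 else 0.0

        j_ex_ms = j_ex_sf = j_fa_sf = 0.0
        if transport:
            tot_m, tot_s, tot_f = a_m + r_m, a_s + r_s, a_f + r_f
            den = k_ex * (tot_m + tot_s) * 0.5 + tot_m * tot_s
            if den > 0.0:
                j_ex_ms = v_ex_mvm * (a_m * r_s - a_s * r_m) / den
            den = k_ex * (tot_s + tot_f) * 0.5 + tot_s * tot_f
            if den > 0.0:
                j_ex_sf = v_ex_bm * (a_s * r_f - a_f * r_s) / den
            j_fa_sf = v_fa_bm * (
                a_s / (k_fa + a_s + p_fa_s) - a_f / (k_fa + a_f + p_fa_f)
            )
        j_dif = v_dif_tracer * (a_m - a_f)
        j_metab = k_metab * a_s

        j_in_m = f_m * a_in_m
        j_out_m = f_m * a_m
        j_in_f = f_f * a_in_f
        j_out_f = f_f * a_f

        dy = np.empty(N_STATE)
        dy[0] = (j_in_m - j_out_m - j_ex_ms - j_dif) / v_m
        dy[1] = 0.0 if clamp else (j_ex_ms - j_ex_sf - j_fa_sf - j_metab) / v_s
        dy[2] = (j_in_f - j_out_f + j_ex_sf + j_fa_sf + j_dif) / v_f
        j_dif_c = v_dif * (c_m - c_f)
        dy[3] = (f_m * (c_in_m - c_m) - j_dif_c) / v_m
        dy[4] = (f_f * (c_in_f - c_f) + j_dif_c) / v_f
        dy[5] = j_metab
        dy[6] = j_in_m
        dy[7] = j_out_m
        dy[8] = j_in_f
        dy[9] = j_out_f
        return dy

    return f
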
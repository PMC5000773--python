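"""Elementary flux laws of the placental transfer model.

Each function returns a net molecular flux in mol/min.  Arguments are
concentrations in mol/l, flows and permeabilities in l/min, maximal rates in
mol/min.  All laws are antisymmetric under exchange of the two compartments
(where that notion applies) and vanish at their respective equilibria.
"""

from __future__ import annotations

__all__ = [
    "exchanger_flux",
    "facilitated_flux",
    "flow_flux",
    "metabolic_flux",
    "diffusion_flux",
]


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value!r}")


def exchanger_flux(
    a_1: float,
    a_2: float,
    r_1: float,
    r_2: float,
    tot_1: float,
    tot_2: float,
    v_ex: float,
    k_ex: float,
) -> float:
    """Net exchanger (antiporter) flux of substrate A from side 1 to side 2.

    Symmetric-carrier exchange kinetics with a single dissociation constant
    ``k_ex`` on both membrane faces:

        J = v_ex * (a_1*r_2 - a_2*r_1)
            / (k_ex*(tot_1 + tot_2)/2 + tot_1*tot_2)

    ``a_i`` is the concentration of the tracked substrate, ``r_i`` the summed
    concentration of all other exchanger substrates (counter-substrates), and
    ``tot_i = a_i + r_i`` the total exchanger substrate on side ``i``.  Net
    flux requires a counter-substrate on the trans side (trans-stimulation):
    the law vanishes whenever ``a_1*r_2 == a_2*r_1``.
    """
    _check_nonneg(a_1=a_1, a_2=a_2, r_1=r_1, r_2=r_2, tot_1=tot_1,
                  tot_2=tot_2, v_ex=v_ex, k_ex=k_ex)
    denom = k_ex * (tot_1 + tot_2) / 2.0 + tot_1 * tot_2
    if denom == 0.0:
        # no substrate anywhere: no carrier turnover, no flux
        return 0.0
    return v_ex * (a_1 * r_2 - a_2 * r_1) / denom


def facilitated_flux(
    a_1: float,
    a_2: float,
    tot_1: float,
    tot_2: float,
    v_fa: float,
    k_fa: float,
) -> float:
    """Net facilitated-transporter (uniporter) flux from side 1 to side 2.

        J = v_fa * (a_1/(k_fa + tot_1) - a_2/(k_fa + tot_2))

    Saturable carrier moving substrate down its gradient; the total substrate
    load ``tot_i`` on the cis side competes for the carrier
    (trans-inhibition by cis load).  |J| < v_fa for all inputs.
    """
    _check_nonneg(a_1=a_1, a_2=a_2, tot_1=tot_1, tot_2=tot_2, v_fa=v_fa)
    if k_fa <= 0:
        raise ValueError(f"k_fa must be positive, got {k_fa!r}")
    return v_fa * (a_1 / (k_fa + tot_1) - a_2 / (k_fa + tot_2))


def flow_flux(flow: float, a_in: float, a: float) -> float:
    """Net flux into a perfused compartment: J = F * (a_in - a).

    The compartment is well mixed, so the venous outflow concentration
    equals the compartment concentration ``a``.
    """
    if flow < 0:
        raise ValueError(f"flow must be nonnegative, got {flow!r}")
    _check_nonneg(a_in=a_in, a=a)
    return flow * (a_in - a)


def metabolic_flux(a_s: float, k_metab: float) -> float:
    """First-order metabolic consumption J = k_metab * a_s (mol/min).

    Linear (unsaturated) kinetics for incorporation of intracellular free
    substrate into the protein pool; release from protein is not modelled.
    """
    _check_nonneg(a_s=a_s, k_metab=k_metab)
    return k_metab * a_s


def diffusion_flux(a_m: float, a_f: float, v_dif: float) -> float:
    """Paracellular diffusive flux maternal → fetal: J = v_dif * (a_m - a_f)."""
    _check_nonneg(a_m=a_m, a_f=a_f, v_dif=v_dif)
    return v_dif * (a_m - a_f)
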
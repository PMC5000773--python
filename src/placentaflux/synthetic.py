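"""Synthetic perfusion-experiment datasets with known ground truth.

Emulates the output structure of the dual-perfusion experiment: for each
placenta, maternal-arterial / maternal-venous / fetal-venous tracer
concentrations sampled at the protocol sample times under the stepwise flow
schedule.  Between-placenta variability enters through cotyledon mass
(mean 42.0 g, SD 9.7 g, truncated above 10 g); compartment volumes, maximal
transport rates, metabolic clearance and diffusive permeability all scale
proportionally with mass (constant transporter density per gram).
Measurement noise is multiplicative lognormal with a given coefficient of
variation, matching how scintillation-counting error scales with signal.

Not emulated: incomplete intervillous mixing, perfusate recovery losses,
quenching — passing tests on these datasets show pipeline correctness, not
robustness to those experimental artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import Inflows
from .params import (
    CompartmentGeometry,
    ModelVariant,
    SubstratePools,
    TransporterParams,
)
from .protocol import FlowProtocol, build_protocol
from .simulate import grid_from_trajectory, simulate

__all__ = ["PerfusionDataset", "generate_dataset", "dataset_summary"]

REFERENCE_MASS = 42.0    # g; defaults in TransporterParams refer to this mass
MASS_SD = 9.7            # g, between-placenta cotyledon-mass SD
MIN_MASS = 10.0          # g, truncation bound


@dataclass(frozen=True)
class PerfusionDataset:
    """Per-placenta venous samples plus derived uptake/transfer.

    ``samples``: long-format table (placenta, mass, segment, f_m, f_f, t,
    t_offset, c_ma, c_mv, c_fv) of (noisy) concentrations in mol/l.
    ``conditions``: one row per placenta x flow combination with uptake and
    transfer (mol/min) computed from the quasi-steady samples, as the
    experiment defines them.  ``true_params`` and ``seed`` record the
    generating ground truth for synthetic data (None for real data).
    """

    samples: pd.DataFrame
    conditions: pd.DataFrame
    masses: np.ndarray
    true_params: TransporterParams | None = None
    variant: ModelVariant | None = None
    noise_cv: float | None = None
    seed: int | None = None

    @property
    def n_placentas(self) -> int:
        return len(self.masses)


def scale_to_mass(
    params: TransporterParams, mass: float, reference_mass: float = REFERENCE_MASS
) -> TransporterParams:
    """Scale extensive rate parameters to a cotyledon of the given mass."""
    s = mass / reference_mass
    return replace(
        params,
        v_ex_mvm=params.v_ex_mvm * s,
        v_ex_bm=params.v_ex_bm * s,
        v_fa_bm=params.v_fa_bm * s,
        k_metab=params.k_metab * s,
        v_dif=params.v_dif * s,
    )


def generate_dataset(
    true_params: TransporterParams,
    variant: ModelVariant,
    n_placentas: int = 5,
    noise_cv: float = 0.1,
    weight_mean: float = REFERENCE_MASS,
    weight_sd: float = MASS_SD,
    seed: int | None = None,
    protocol: FlowProtocol | None = None,
    pools: SubstratePools | None = None,
    inflows: Inflows | None = None,
) -> PerfusionDataset:
    """Simulate the perfusion experiment for ``n_placentas`` cotyledons.

    Each placenta gets its own cotyledon mass (normal, truncated above
    ``MIN_MASS`` g) with geometry and rate parameters scaled to it, a full
    protocol simulation, and lognormal measurement noise with coefficient
    of variation ``noise_cv`` applied to every sampled venous
    concentration.  Reproducible under a fixed ``seed``.
    """
    if n_placentas < 1:
        raise ValueError("n_placentas must be >= 1")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be nonnegative, got {noise_cv!r}")
    if weight_mean <= MIN_MASS or weight_sd < 0:
        raise ValueError("invalid cotyledon weight parameters")
    rng = np.random.default_rng(seed)
    if protocol is None:
        protocol = build_protocol()
    if pools is None:
        pools = SubstratePools.tracer()
    if inflows is None:
        inflows = Inflows()

    # mean-one lognormal noise: exp(N(-s^2/2, s)), s^2 = ln(1 + cv^2)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    masses = np.empty(n_placentas)
    for i in range(n_placentas):
        m = rng.normal(weight_mean, weight_sd)
        while m <= MIN_MASS:
            m = rng.normal(weight_mean, weight_sd)
        masses[i] = m

    sample_frames, condition_frames = [], []
    for i, mass in enumerate(masses):
        geom = CompartmentGeometry(cotyledon_mass=mass)
        params_i = scale_to_mass(true_params, mass)
        traj = simulate(protocol, params_i, pools, geom, variant,
                        inflows=inflows)
        s = traj.samples.copy()
        if noise_cv > 0:
            for col in ("c_mv", "c_fv"):
                noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(s))
                s[col] = s[col] * noise
        s.insert(0, "placenta", i)
        s.insert(1, "mass", mass)
        sample_frames.append(s)

        cond = _conditions_from_samples(s, traj.protocol)
        cond.insert(0, "placenta", i)
        cond.insert(1, "mass", mass)
        condition_frames.append(cond)

    return PerfusionDataset(
        samples=pd.concat(sample_frames, ignore_index=True),
        conditions=pd.concat(condition_frames, ignore_index=True),
        masses=masses,
        true_params=true_params,
        variant=variant,
        noise_cv=noise_cv,
        seed=seed,
    )


def _conditions_from_samples(
    samples: pd.DataFrame, protocol: FlowProtocol,
    steady_offsets=(15.0, 18.0),
) -> pd.DataFrame:
    """Uptake/transfer per flow combination from the steady-state samples."""
    rows = []
    for i_seg, seg in enumerate(protocol.segments):
        if seg.label != "experimental":
            continue
        sub = samples[(samples["segment"] == i_seg)
                      & samples["t_offset"].isin(steady_offsets)]
        if sub.empty:
            continue
        uptake = float(((sub["c_ma"] - sub["c_mv"]) * seg.f_m).mean())
        transfer = float((sub["c_fv"] * seg.f_f).mean())
        rows.append({"segment": i_seg, "f_m": seg.f_m, "f_f": seg.f_f,
                     "uptake": uptake, "transfer": transfer})
    return pd.DataFrame(rows)


def dataset_summary(dataset: PerfusionDataset) -> pd.DataFrame:
    """Per-condition means ± SE of uptake and transfer across placentas.

    Returns the 9-condition table (f_m, f_f, uptake_mean, uptake_se,
    transfer_mean, transfer_se, n).  With a single placenta the SE columns
    are NaN (flagged, not an error), since a between-placenta SE is
    undefined at n = 1.
    """
    g = dataset.conditions.groupby(["f_m", "f_f"], sort=True)
    out = g.agg(
        uptake_mean=("uptake", "mean"),
        uptake_se=("uptake", "sem"),
        transfer_mean=("transfer", "mean"),
        transfer_se=("transfer", "sem"),
        n=("uptake", "size"),
    ).reset_index()
    return out
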
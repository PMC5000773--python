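"""Parameter, geometry, pool and state containers for the placental transfer model.

All quantities are kept in an SI-like internal unit system: mol, liters,
minutes.  Conversions from the conventional experimental units (µmol/l,
nmol/l, ml/min, grams of tissue) happen only at construction / I-O
boundaries.

The model describes a perfused human placental cotyledon as three
well-mixed compartments — maternal intervillous space (m),
syncytiotrophoblast (s) and fetal capillary (f) — connected by

* an amino-acid *exchanger* (antiporter) on the microvillous membrane
  (MVM, maternal-facing) and on the basal membrane (BM, fetal-facing),
* a *facilitated transporter* (uniporter) on the BM,
* a paracellular *diffusion* pathway between maternal and fetal plasma,
* first-order intracellular *metabolism* (protein incorporation), and
* perfusate *flow* through the maternal and fetal circuits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import yaml

__all__ = [
    "TransporterParams",
    "CompartmentGeometry",
    "SubstratePools",
    "CompartmentState",
    "ModelVariant",
    "SYNCYTIO_POOL_FA_EX",
    "SYNCYTIO_POOL_EX_ONLY",
    "MATERNAL_PHYS_POOL_FA_EX",
    "MATERNAL_PHYS_POOL_EX_ONLY",
    "TRACER_INFLOW",
    "CREATININE_INFLOW",
]

# Generic amino-acid pool concentrations (mol/l).  Two generic substrates are
# distinguished: one transported by both facilitated transporters and
# exchangers (includes phenylalanine), one by exchangers only.
SYNCYTIO_POOL_FA_EX = 3_132e-6
SYNCYTIO_POOL_EX_ONLY = 4_491e-6
# Maternal arterial pools under physiological amino-acid concentrations.
MATERNAL_PHYS_POOL_FA_EX = 615e-6
MATERNAL_PHYS_POOL_EX_ONLY = 915e-6

# Default perfusate inflow concentrations (mol/l).
TRACER_INFLOW = 2.7e-9          # [14C]phenylalanine in maternal artery
CREATININE_INFLOW = 1.8e-3      # paracellular-diffusion marker


def _require_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class TransporterParams:
    """Kinetic constants of the transfer pathways.

    Parameters
    ----------
    k_ex, k_fa
        Dissociation constants of the exchanger and the facilitated
        transporter (mol/l).  The carriers are symmetric: the same K applies
        on both membrane faces.
    v_ex_mvm, v_ex_bm
        Maximal exchange rates at the microvillous and basal membranes
        (mol/min).
    v_fa_bm
        Maximal facilitated-transport rate at the basal membrane (mol/min).
    k_metab
        First-order metabolic clearance of intracellular free substrate
        (l/min); converts free tracer into the protein-incorporated pool.
    v_dif
        Effective paracellular diffusive permeability (l/min), shared by the
        creatinine marker and, when enabled, the tracer.
    shared_bm_vmax
        If true (default), the BM exchanger and BM facilitated transporter
        are constrained to the same Vmax and ``v_ex_bm == v_fa_bm`` is
        enforced.

    The maximal-rate and clearance defaults are calibrated so that the
    simulated experiment reproduces the reference perfused-cotyledon
    measurements: mean steady-state uptake ≈ 2.2e-11 mol/min, ~15 % of
    uptake transferred to the fetal circuit, and intracellular free tracer
    ≈ 163 nmol/l (see docs/methods.md for the derivation).
    """

    k_ex: float = 200e-6
    k_fa: float = 1_000e-6
    v_ex_mvm: float = 1.9e-6
    v_ex_bm: float = 9.7e-8
    v_fa_bm: float = 9.7e-8
    k_metab: float = 1.15e-4
    v_dif: float = 2.0e-3
    shared_bm_vmax: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "shared_bm_vmax":
                continue
            _require_nonneg(f.name, getattr(self, f.name))
        if self.shared_bm_vmax and self.v_ex_bm != self.v_fa_bm:
            raise ValueError(
                "shared_bm_vmax requires v_ex_bm == v_fa_bm "
                f"(got {self.v_ex_bm!r} and {self.v_fa_bm!r})"
            )

    def with_bm_vmax(self, v_bm: float) -> "TransporterParams":
        """Return a copy with both BM maximal rates set to ``v_bm``."""
        return replace(self, v_ex_bm=v_bm, v_fa_bm=v_bm)

    # -- flat text-config round trip -------------------------------------
    _CONFIG_KEYS = {
        "k_ex": "k_ex_mol_per_l",
        "k_fa": "k_fa_mol_per_l",
        "v_ex_mvm": "v_ex_mvm_mol_per_min",
        "v_ex_bm": "v_ex_bm_mol_per_min",
        "v_fa_bm": "v_fa_bm_mol_per_min",
        "k_metab": "k_metab_l_per_min",
        "v_dif": "v_dif_l_per_min",
        "shared_bm_vmax": "shared_bm_vmax",
    }

    def to_config(self) -> dict:
        """Flat dict with explicit unit suffixes in the key names."""
        return {key: getattr(self, attr) for attr, key in self._CONFIG_KEYS.items()}

    @classmethod
    def from_config(cls, config: Mapping) -> "TransporterParams":
        inverse = {key: attr for attr, key in cls._CONFIG_KEYS.items()}
        unknown = set(config) - set(inverse)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{inverse[k]: v for k, v in config.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TransporterParams":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


@dataclass(frozen=True)
class CompartmentGeometry:
    """Volumes of the three compartments, derived from cotyledon mass.

    The cotyledon (default 42 g at 1 ml/g) is partitioned by volume
    fractions: intervillous space 0.25, syncytiotrophoblast 0.15, fetal
    capillaries 0.05 (remainder: villous stroma and non-exchanging tissue).
    The trophoblast fraction 0.15 is also the value used for
    tissue-concentration estimates in the tracer accounting.
    """

    cotyledon_mass: float = 42.0          # g
    density: float = 1.0                  # ml per g tissue
    frac_m: float = 0.25
    frac_s: float = 0.15
    frac_f: float = 0.05

    def __post_init__(self) -> None:
        if self.cotyledon_mass <= 0 or self.density <= 0:
            raise ValueError("cotyledon mass and density must be positive")
        for name in ("frac_m", "frac_s", "frac_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frac_m + self.frac_s + self.frac_f > 1.0 + 1e-12:
            raise ValueError("compartment fractions exceed the cotyledon volume")

    @property
    def cotyledon_volume(self) -> float:
        """Total cotyledon volume in liters."""
        return self.cotyledon_mass * self.density * 1e-3

    @property
    def v_m(self) -> float:
        return self.frac_m * self.cotyledon_volume

    @property
    def v_s(self) -> float:
        return self.frac_s * self.cotyledon_volume

    @property
    def v_f(self) -> float:
        return self.frac_f * self.cotyledon_volume


@dataclass(frozen=True)
class SubstratePools:
    """Fixed generic amino-acid pool concentrations (mol/l) per compartment.

    ``fa_ex_*`` are substrates of both facilitated transporters and
    exchangers; ``ex_only_*`` are substrates of exchangers only.  Pools are
    boundary conditions, not state: they are held constant throughout a
    simulation.  In tracer mode the maternal and fetal perfusates contain no
    transporter substrates besides the tracer itself, so those pools are 0.
    """

    fa_ex_m: float = 0.0
    fa_ex_s: float = SYNCYTIO_POOL_FA_EX
    fa_ex_f: float = 0.0
    ex_only_m: float = 0.0
    ex_only_s: float = SYNCYTIO_POOL_EX_ONLY
    ex_only_f: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_nonneg(f.name, getattr(self, f.name))

    @classmethod
    def tracer(cls) -> "SubstratePools":
        """Pools for the tracer experiment: substrate-free perfusates."""
        return cls()

    @classmethod
    def physiological(cls) -> "SubstratePools":
        """Pools with physiological maternal arterial amino-acid levels."""
        return cls(
            fa_ex_m=MATERNAL_PHYS_POOL_FA_EX,
            ex_only_m=MATERNAL_PHYS_POOL_EX_ONLY,
        )

    # Exchanger substrates: both generic pools (plus the tracer, added by
    # the flux assembly).  Facilitated substrates: fa_ex pool only.
    def exchanger_pool(self, compartment: str) -> float:
        return getattr(self, f"fa_ex_{compartment}") + getattr(
            self, f"ex_only_{compartment}"
        )

    def facilitated_pool(self, compartment: str) -> float:
        return getattr(self, f"fa_ex_{compartment}")


@dataclass
class CompartmentState:
    """Dynamic species: free tracer, creatinine marker, protein pool.

    Concentrations in mol/l; ``protein`` is the cumulative amount (mol) of
    tracer metabolized into the protein pool (non-decreasing along any
    trajectory; release from protein is not modelled).
    """

    a_m: float = 0.0
    a_s: float = 0.0
    a_f: float = 0.0
    c_m: float = 0.0
    c_f: float = 0.0
    protein: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_nonneg(f.name, getattr(self, f.name))


@dataclass(frozen=True)
class ModelVariant:
    """Which transfer mechanisms operate on the tracer.

    ``clamp_intracellular`` freezes the syncytiotrophoblast free-tracer
    concentration at its current value (dA_s/dt = 0), emulating perfect
    intracellular homeostasis.  The creatinine marker always moves by flow
    and diffusion irrespective of these flags.
    """

    transport_enabled: bool = True
    diffusion_enabled: bool = False
    metabolism_enabled: bool = True
    clamp_intracellular: bool = False

    def __post_init__(self) -> None:
        if not (self.transport_enabled or self.diffusion_enabled):
            raise ValueError("at least one transfer mechanism must be enabled")

    @classmethod
    def diffusion(cls) -> "ModelVariant":
        """Simple paracellular diffusion only."""
        return cls(transport_enabled=False, diffusion_enabled=True,
                   metabolism_enabled=False)

    @classmethod
    def transport(cls) -> "ModelVariant":
        """Carrier-mediated transport without intracellular metabolism."""
        return cls(transport_enabled=True, diffusion_enabled=False,
                   metabolism_enabled=False)

    @classmethod
    def transport_metabolism(cls) -> "ModelVariant":
        """Carrier-mediated transport with first-order metabolism (default)."""
        return cls(transport_enabled=True, diffusion_enabled=False,
                   metabolism_enabled=True)

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        presets = {
            "diffusion": cls.diffusion,
            "transport": cls.transport,
            "transport+metabolism": cls.transport_metabolism,
        }
        try:
            return presets[name]()
        except KeyError:
            raise ValueError(
                f"unknown variant {name!r}; expected one of {sorted(presets)}"
            ) from None
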
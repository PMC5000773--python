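"""Tracer bookkeeping for the perfused-cotyledon experiment.

Implements the experimental arithmetic applied to scintillation-count data:
quench correction of the protein pellet, uptake/transfer mass balance,
free/protein partition and recovery, and the estimate of the free-tracer
concentration in trophoblast tissue used to infer the basal-membrane
concentration gradient.  Amounts are in nmol per cotyledon unless noted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "TracerAccount",
    "quench_correct",
    "mass_balance",
    "percent_transferred",
    "recovery_fraction",
    "tissue_concentration",
    "bm_gradient",
    "build_account",
]

DEFAULT_TROPHOBLAST_FRACTION = 0.15
DEFAULT_PELLET_EFFICIENCY = 0.31


def quench_correct(counts: float, efficiency: float) -> float:
    """Scale scintillation counts by the counting efficiency.

    The protein pellet quenches emission (efficiency 0.31 by default
    elsewhere); corrected counts = counts / efficiency.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency!r}")
    if counts < 0:
        raise ValueError(f"counts must be nonnegative, got {counts!r}")
    return counts / efficiency


def mass_balance(uptake: float, transferred: float) -> float:
    """Tracer retained in the cotyledon: uptake − transferred (nmol)."""
    if not uptake >= transferred >= 0:
        raise ValueError(
            f"need uptake >= transferred >= 0, got {uptake!r}, {transferred!r}"
        )
    return uptake - transferred


def percent_transferred(uptake: float, transferred: float) -> float:
    """Share of uptake delivered to the fetal circuit, in percent."""
    if uptake <= 0:
        raise ValueError(f"uptake must be positive, got {uptake!r}")
    if transferred < 0:
        raise ValueError(f"transferred must be nonnegative, got {transferred!r}")
    return 100.0 * transferred / uptake


def recovery_fraction(free: float, protein: float, retained: float) -> float:
    """Recovered share of retained tracer, in percent.

    ``free`` and ``protein`` are the tracer amounts measured in the tissue
    supernatant and (quench-corrected) protein pellet; ``retained`` comes
    from the perfusate mass balance.  Values above 100 % are flagged.
    """
    if retained <= 0:
        raise ValueError(f"retained must be positive, got {retained!r}")
    if free < 0 or protein < 0:
        raise ValueError("free and protein amounts must be nonnegative")
    pct = 100.0 * (free + protein) / retained
    if pct > 100.0:
        warnings.warn(
            f"recovery {pct:.1f}% exceeds retained tracer", RuntimeWarning,
            stacklevel=2)
    return pct


def tissue_concentration(
    free: float,
    wet_weight: float,
    trophoblast_fraction: float = DEFAULT_TROPHOBLAST_FRACTION,
    density: float = 1.0,
) -> float:
    """Free-tracer concentration in trophoblast tissue (nmol/l).

    Distributes the free tracer amount (nmol/cotyledon) over the trophoblast
    water volume: wet weight (g) x density (ml/g) x trophoblast volume
    fraction, converted to liters.
    """
    if free <= 0 or wet_weight <= 0 or density <= 0:
        raise ValueError("free amount, wet weight and density must be positive")
    if not 0.0 < trophoblast_fraction <= 1.0:
        raise ValueError(
            f"trophoblast fraction must be in (0, 1], got {trophoblast_fraction!r}"
        )
    volume_l = wet_weight * density * trophoblast_fraction * 1e-3
    return free / volume_l


def bm_gradient(tissue_conc: float, fetal_vein_conc: float) -> float:
    """Concentration ratio across the basal membrane (tissue / fetal vein)."""
    if fetal_vein_conc <= 0:
        raise ValueError(
            f"fetal vein concentration must be positive, got {fetal_vein_conc!r}"
        )
    if tissue_conc < 0:
        raise ValueError(f"tissue concentration must be nonnegative")
    return tissue_conc / fetal_vein_conc


@dataclass(frozen=True)
class TracerAccount:
    """Complete tracer account for one perfused cotyledon (amounts in nmol)."""

    uptake: float
    transferred: float
    retained: float
    free: float
    protein: float
    recovery_percent: float
    percent_transferred: float
    tissue_concentration: float     # nmol/l
    counting_efficiency: float = DEFAULT_PELLET_EFFICIENCY

    def __post_init__(self) -> None:
        if abs(self.retained - (self.uptake - self.transferred)) > 1e-9 * max(
            1.0, self.uptake
        ):
            raise ValueError("retained must equal uptake - transferred")
        if not 0.0 < self.counting_efficiency <= 1.0:
            raise ValueError("counting efficiency must be in (0, 1]")


def build_account(
    uptake: float,
    transferred: float,
    free: float,
    protein: float,
    wet_weight: float,
    trophoblast_fraction: float = DEFAULT_TROPHOBLAST_FRACTION,
    density: float = 1.0,
    counting_efficiency: float = DEFAULT_PELLET_EFFICIENCY,
) -> TracerAccount:
    """Assemble the full, mutually consistent tracer account."""
    retained = mass_balance(uptake, transferred)
    return TracerAccount(
        uptake=uptake,
        transferred=transferred,
        retained=retained,
        free=free,
        protein=protein,
        recovery_percent=recovery_fraction(free, protein, retained),
        percent_transferred=percent_transferred(uptake, transferred),
        tissue_concentration=tissue_concentration(
            free, wet_weight, trophoblast_fraction, density
        ),
        counting_efficiency=counting_efficiency,
    )
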
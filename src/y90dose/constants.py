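"""Physical constants for yttrium-90 dosimetry.

All engines share one set of constants: the mean beta energy per
disintegration, the physical half-life (microspheres are permanent implants,
so cumulated activity is purely physical decay), and the reference densities
of soft tissue and lung used for kernel construction and range scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PhysicsConstants", "Y90"]


@dataclass(frozen=True)
class PhysicsConstants:
    """Constants of the ⁹⁰Y beta decay and the reference media.

    Attributes
    ----------
    e_avg_mev : float
        Average beta energy per disintegration (MeV).
    t_half_h : float
        Physical half-life (hours).
    e_max_mev : float
        Beta spectrum endpoint energy (MeV).
    r_max_soft_mm : float
        Maximum beta range in reference soft tissue (mm at ``rho_ref``).
    rho_ref : float
        Reference soft-tissue density (g/cc) of the dose kernel medium.
    rho_lung_ref : float
        Nominal lung density (g/cc).
    gy_per_mev_per_g : float
        Unit conversion, Gy per (MeV deposited per gram).
    """

    e_avg_mev: float = 0.937
    t_half_h: float = 64.1
    e_max_mev: float = 2.28
    r_max_soft_mm: float = 11.0
    rho_ref: float = 1.04
    rho_lung_ref: float = 0.26
    gy_per_mev_per_g: float = 1.602176e-10

    def __post_init__(self) -> None:
        for name in (
            "e_avg_mev",
            "t_half_h",
            "e_max_mev",
            "r_max_soft_mm",
            "rho_ref",
            "rho_lung_ref",
            "gy_per_mev_per_g",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def t_half_s(self) -> float:
        return self.t_half_h * 3600.0

    @property
    def decays_per_bq(self) -> float:
        """Total disintegrations per Bq of initial activity (no clearance)."""
        return self.t_half_s / math.log(2.0)

    def r_max_mm(self, rho: float) -> float:
        """Maximum beta range in a medium of density ``rho`` (g/cc)."""
        if rho <= 0:
            raise ValueError("density must be positive")
        return self.r_max_soft_mm * self.rho_ref / rho


#: Default constants instance shared by all modules.
Y90 = PhysicsConstants()
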
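"""The four voxel dose engines and the counts -> activity -> decays chain.

Engines (all return absorbed dose in Gy per voxel):

* **LD** (local deposition): every disintegration deposits its mean beta
  energy in its own voxel, ``D = N * E_avg / (rho * dV)``.  Exact under
  charged-particle equilibrium.
* **SK** (soft-tissue kernel): 3D convolution of the per-voxel
  disintegrations with the reference soft-tissue voxel kernel.  Assumes
  1.04 g/cc everywhere, so it underestimates dose in lung by rho/1.04.
* **SKD** (density-corrected kernel): the SK dose rescaled voxelwise by
  1.04/rho.
* **RT** (reference transport): deterministic kernel summation along
  radiological (density-scaled) paths; reduces exactly to the correct
  equilibrium dose in uniform media of any density and reproduces the
  range stretching of the beta kernel in low-density lung.  It is this
  package's reference ("truth") engine.

The activity chain follows post-therapy ⁹⁰Y microsphere imaging practice:
counts are self-calibrated so their total equals the administered activity,
and cumulated disintegrations assume pure physical decay (permanent implant,
no biological clearance): ``N = A * T_half / ln 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from ._transport import rt_accumulate, slab_range_tables
from .constants import Y90, PhysicsConstants
from .grid import VoxelGrid
from .kernel import DosePointKernel, TransportTables, VoxelKernel, transport_tables

__all__ = [
    "DoseMap",
    "SelfCalibration",
    "counts_to_activity",
    "activity_to_disintegrations",
    "dose_ld",
    "dose_sk",
    "dose_skd",
    "dose_rt",
    "global_energy",
]

log = logging.getLogger(__name__)

#: Fraction of the map maximum below which a negative convolution residue is
#: considered numerical noise (clamped to zero silently; larger residues are
#: logged).
_NEGATIVE_CLAMP_REL = 1e-6


@dataclass
class DoseMap:
    """A per-voxel absorbed dose map (Gy) tagged with its engine."""

    grid: VoxelGrid
    engine: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.grid.values
        if not np.all(np.isfinite(v)):
            raise ValueError("dose map must be finite everywhere")
        if np.any(v < 0):
            raise ValueError("dose map must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class SelfCalibration:
    """Administered activity / total counts scaling."""

    administered_bq: float
    total_counts: float

    def __post_init__(self) -> None:
        if self.total_counts <= 0:
            raise ValueError("total counts must be positive")
        if self.administered_bq <= 0:
            raise ValueError("administered activity must be positive")

    @property
    def factor(self) -> float:
        return self.administered_bq / self.total_counts


def counts_to_activity(counts: VoxelGrid, administered_bq: float) -> VoxelGrid:
    """Self-calibrate reconstructed counts to activity (Bq per voxel).

    ``A = C * administered / sum(C)``; the total activity equals the
    administered activity exactly, making the result invariant to any
    overall counts scale.
    """
    total = counts.total()
    if total <= 0:
        raise ValueError("counts must have a positive total")
    cal = SelfCalibration(administered_bq=administered_bq, total_counts=total)
    return counts.with_values(counts.values * cal.factor)


def activity_to_disintegrations(
    a: VoxelGrid, constants: PhysicsConstants = Y90
) -> VoxelGrid:
    """Total disintegrations per voxel, ``N = A * T_half / ln 2``."""
    if np.any(a.values < 0):
        raise ValueError("activity must be non-negative")
    return a.with_values(a.values * constants.decays_per_bq)


def _check_coregistered(a: VoxelGrid, b: VoxelGrid) -> None:
    if a.dims != b.dims or not np.allclose(a.spacing, b.spacing):
        raise ValueError("grids must be co-registered (same dims and spacing)")


def dose_ld(
    n: VoxelGrid, rho: VoxelGrid, constants: PhysicsConstants = Y90
) -> DoseMap:
    """Local deposition dose: ``D = N * E_avg / (rho * dV)`` in Gy."""
    _check_coregistered(n, rho)
    active = n.values > 0
    if np.any(rho.values[active] <= 0):
        raise ValueError("zero or negative density at an active voxel")
    mass_g = np.where(rho.values > 0, rho.values, np.inf) * n.voxel_volume_cc
    dose = n.values * constants.e_avg_mev / mass_g * constants.gy_per_mev_per_g
    return DoseMap(grid=n.with_values(dose), engine="LD")


def _clamp_negative(values: np.ndarray, engine: str) -> np.ndarray:
    neg = values < 0
    if np.any(neg):
        worst = float(-values[neg].min())
        if worst > _NEGATIVE_CLAMP_REL * float(values.max(initial=0.0)):
            log.warning(
                "%s: clamping negative residue down to -%.3e Gy", engine, worst
            )
        values = np.where(neg, 0.0, values)
    return values


def dose_sk(n: VoxelGrid, k: VoxelKernel) -> DoseMap:
    """Soft-tissue kernel dose: zero-padded convolution of N with K (Gy).

    The FFT convolution is linear (zero-padded), so there is no wrap-around;
    tiny negative numerical residues are clamped to zero.
    """
    spacing = n.require_isotropic()
    if abs(spacing - k.voxel_mm) > 1e-6:
        raise ValueError(
            f"voxel-size mismatch: grid {spacing} mm vs kernel {k.voxel_mm} mm"
        )
    dose = fftconvolve(n.values, k.values, mode="same")
    dose = _clamp_negative(dose, "SK")
    return DoseMap(grid=n.with_values(dose), engine="SK")


def dose_skd(n: VoxelGrid, k: VoxelKernel, rho: VoxelGrid) -> DoseMap:
    """Density-corrected kernel dose: ``SK * rho_ref / rho`` voxelwise."""
    _check_coregistered(n, rho)
    if np.any(rho.values <= 0):
        raise ValueError("density must be positive everywhere for SKD")
    sk = dose_sk(n, k)
    dose = sk.values * (k.rho_ref / rho.values)
    return DoseMap(grid=n.with_values(dose), engine="SKD")


_TABLE_CACHE: dict[tuple[int, float], TransportTables] = {}


def _tables_for(dpk: DosePointKernel, voxel_mm: float) -> TransportTables:
    key = (id(dpk), round(voxel_mm, 6))
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = transport_tables(dpk, voxel_mm=voxel_mm)
    return _TABLE_CACHE[key]


def dose_rt(
    n: VoxelGrid,
    rho: VoxelGrid,
    dpk: DosePointKernel,
    target_mask: np.ndarray | None = None,
    tables: TransportTables | None = None,
    constants: PhysicsConstants = Y90,
    max_window_voxels: int = 32,
) -> DoseMap:
    """Reference transport dose by radiological-distance kernel summation.

    For each target voxel t the engine sums over source voxels s,

    ``D(t) = sum_s N_s * phi(l_eff) * (l_eff / l_geo)^3 * (rho_ref / rho_t)``

    where ``l_eff`` is the density-weighted (radiological) path length
    between the voxel centers, and ``phi`` the pair-averaged kernel profile.
    Pairs with ``l_eff`` beyond the kernel support contribute nothing.  In a
    uniform medium of any density this reduces to the density-scaled kernel
    and reproduces local-deposition dose in the interior.

    ``target_mask`` restricts the (expensive) computation to the voxels that
    are actually analyzed; other voxels are left at zero dose.
    """
    spacing = n.require_isotropic()
    _check_coregistered(n, rho)
    if np.any(rho.values <= 0):
        raise ValueError("density must be positive everywhere for transport")
    if tables is None:
        tables = _tables_for(dpk, spacing)
    if abs(tables.voxel_mm - spacing) > 1e-6:
        raise ValueError("transport tables were built for a different voxel size")

    if target_mask is None:
        targets = np.argwhere(np.ones(n.dims, dtype=bool))
    else:
        if target_mask.shape != n.dims:
            raise ValueError("target mask shape must match the grid")
        targets = np.argwhere(target_mask.astype(bool))
    targets = np.ascontiguousarray(targets.astype(np.int64))

    rho_arr = np.ascontiguousarray(rho.values.astype(np.float64))
    n_arr = np.ascontiguousarray(n.values.astype(np.float64))
    rngmin, rngmax = slab_range_tables(rho_arr)
    rho_min = float(rho_arr.min())
    win = int(np.ceil(tables.r_cutoff_mm * tables.rho_ref / (rho_min * spacing)))
    win = min(win, max_window_voxels, max(n.dims))

    out = np.zeros(n.dims, dtype=np.float64)
    rt_accumulate(
        n_arr,
        rho_arr,
        targets,
        float(spacing),
        np.ascontiguousarray(tables.phi_pair),
        float(tables.r_grid[1] - tables.r_grid[0]),
        float(tables.r_cutoff_mm),
        np.ascontiguousarray(tables.s_grid),
        np.ascontiguousarray(tables.self_bracket),
        float(tables.rho_ref),
        win,
        rngmin,
        rngmax,
        out,
    )
    dose = _clamp_negative(out * constants.gy_per_mev_per_g, "RT")
    return DoseMap(
        grid=n.with_values(dose),
        engine="RT",
        meta={"masked": target_mask is not None, "window_voxels": win},
    )


def global_energy(
    d: DoseMap | VoxelGrid, rho: VoxelGrid, constants: PhysicsConstants = Y90
) -> float:
    """Total deposited energy of a dose map, ``sum(D * rho * dV)`` in MeV."""
    grid = d.grid if isinstance(d, DoseMap) else d
    _check_coregistered(grid, rho)
    mass_g = rho.values * grid.voxel_volume_cc
    return float((grid.values * mass_g).sum() / constants.gy_per_mev_per_g)
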
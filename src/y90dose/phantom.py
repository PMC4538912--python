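"""Deterministic synthetic SPECT/CT-like phantoms and cohorts.

Each phantom "patient" is a co-registered bundle on one isotropic grid:

* a density volume — soft tissue (1.04 g/cc) below a horizontal liver-lung
  interface plane, lung (0.26 g/cc) above it;
* a true activity volume — liver-dominant uptake in an ellipsoidal liver
  (clipped at the interface) with focal spherical tumors at an elevated
  uptake ratio, plus a lung shunt fraction LS of the administered activity
  spread uniformly through the lung volume of interest;
* binary masks for liver, each tumor, NL (liver minus tumors), and the
  right-lung VOI;
* simulated counts: the activity blurred by the imaging point-spread
  function (default 20 mm FWHM), scaled, with optional Poisson noise.

The top lung slabs form an inactive padding region outside every VOI, so
beta energy escaping upward from the active lung stays on the grid.  All
sampling is driven by explicit seeds: a fixed seed reproduces bit-identical
volumes and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .constants import Y90
from .grid import VoxelGrid

__all__ = [
    "TumorSpec",
    "PhantomSpec",
    "PhantomBundle",
    "CohortSpec",
    "generate_phantom",
    "simulate_imaging",
    "generate_cohort",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class TumorSpec:
    """A spherical tumor: center (mm, world), radius (mm), uptake ratio."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    uptake_ratio: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if self.uptake_ratio <= 0:
            raise ValueError("uptake ratio must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and study conditions of one synthetic patient."""

    dims: tuple[int, int, int] = (42, 42, 52)
    spacing_mm: float = 4.8
    lung_z_start: int = 30  # first z index of the lung half-space
    lung_layers: int = 12  # active lung layers forming the RL VOI
    liver_center_mm: tuple[float, float, float] | None = None
    liver_radii_mm: tuple[float, float, float] = (65.0, 60.0, 52.0)
    tumors: tuple[TumorSpec, ...] = ()
    ls: float = 0.05
    administered_bq: float = 2.81e9
    fwhm_mm: float = 20.0
    counts_scale: float = 1e-4
    poisson_noise: bool = False
    seed: int = 0
    rho_soft: float = Y90.rho_ref
    rho_lung: float = Y90.rho_lung_ref

    def __post_init__(self) -> None:
        if not 0.0 <= self.ls <= 1.0:
            raise ValueError("lung shunt fraction must lie in [0, 1]")
        if any(r <= 0 for r in self.liver_radii_mm):
            raise ValueError("liver radii must be positive")
        if not 0 < self.lung_z_start < self.dims[2]:
            raise ValueError("lung_z_start must lie inside the grid")
        if self.lung_z_start + self.lung_layers > self.dims[2]:
            raise ValueError("active lung layers exceed the grid")
        if self.administered_bq <= 0 or self.counts_scale <= 0:
            raise ValueError("administered activity and counts scale must be positive")

    @property
    def interface_z_mm(self) -> float:
        """World z of the liver-lung interface plane."""
        return (self.lung_z_start - 0.5) * self.spacing_mm

    def default_liver_center(self) -> tuple[float, float, float]:
        sp = self.spacing_mm
        return (
            (self.dims[0] - 1) / 2.0 * sp,
            (self.dims[1] - 1) / 2.0 * sp,
            self.interface_z_mm - 0.62 * self.liver_radii_mm[2],
        )


@dataclass
class PhantomBundle:
    """One synthetic patient: volumes, masks, and its generating spec."""

    spec: PhantomSpec
    density: VoxelGrid
    activity: VoxelGrid
    counts: VoxelGrid
    masks: dict[str, np.ndarray]

    @property
    def administered_bq(self) -> float:
        return self.spec.administered_bq


def _voxel_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sp = spec.spacing_mm
    nx, ny, nz = spec.dims
    return (
        np.arange(nx)[:, None, None] * sp,
        np.arange(ny)[None, :, None] * sp,
        np.arange(nz)[None, None, :] * sp,
    )


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build density, true activity, masks, and simulated counts.

    Total activity equals the administered activity exactly: the fraction
    LS is spread uniformly over the right-lung VOI and 1-LS over the liver,
    with tumor voxels weighted by their uptake ratio relative to NL.
    """
    nx, ny, nz = spec.dims
    sp = spec.spacing_mm
    x, y, z = _voxel_centers(spec)

    lung_half = np.broadcast_to(z >= spec.lung_z_start * sp - sp / 2, spec.dims)
    density = np.where(lung_half, spec.rho_lung, spec.rho_soft)

    cx, cy, cz = spec.liver_center_mm or spec.default_liver_center()
    ax, ay, az = spec.liver_radii_mm
    ellipsoid = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    liver = ellipsoid & ~lung_half

    tumors = np.zeros(spec.dims, dtype=bool)
    tumor_masks: dict[str, np.ndarray] = {}
    weights = np.zeros(spec.dims)
    weights[liver] = 1.0
    for i, t in enumerate(spec.tumors):
        tx, ty, tz = t.center_mm
        sphere = (x - tx) ** 2 + (y - ty) ** 2 + (z - tz) ** 2 <= t.radius_mm**2
        if not sphere.any():
            raise ValueError(f"tumor {i} covers no voxel")
        if np.any(sphere & ~liver):
            raise ValueError(f"tumor {i} escapes the liver")
        tumor_masks[f"tumor_{i}"] = sphere
        tumors |= sphere
        weights[sphere] = t.uptake_ratio
    nl = liver & ~tumors

    rl = np.zeros(spec.dims, dtype=bool)
    rl[:, :, spec.lung_z_start : spec.lung_z_start + spec.lung_layers] = True
    rl &= lung_half

    activity = np.zeros(spec.dims)
    if not liver.any():
        raise ValueError("liver mask is empty")
    activity[liver] = weights[liver] / weights[liver].sum() * (1.0 - spec.ls)
    activity[rl] += spec.ls / rl.sum()
    activity *= spec.administered_bq

    grid = VoxelGrid(density, (sp,) * 3)
    act_grid = grid.with_values(activity)
    counts = simulate_imaging(
        act_grid,
        fwhm_mm=spec.fwhm_mm,
        counts_scale=spec.counts_scale,
        noise=spec.poisson_noise,
        seed=spec.seed,
    )
    masks = {"liver": liver, "nl": nl, "tumors": tumors, "rl": rl, **tumor_masks}
    return PhantomBundle(
        spec=spec, density=grid, activity=act_grid, counts=counts, masks=masks
    )


def simulate_imaging(
    true_activity: VoxelGrid,
    fwhm_mm: float,
    counts_scale: float = 1.0,
    noise: bool = False,
    seed: int = 0,
) -> VoxelGrid:
    """Proportional counts model: PSF blur, scale, optional Poisson noise.

    The blur uses reflective boundaries so the total stays on the grid (the
    field-of-view analogue of self-calibration making absolute scale
    irrelevant).  With ``noise=False`` the chain is fully deterministic;
    with noise, the same seed reproduces identical counts.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if counts_scale <= 0:
        raise ValueError("counts scale must be positive")
    values = true_activity.values.astype(float)
    if fwhm_mm > 0:
        sigma_vox = [fwhm_mm / _FWHM_TO_SIGMA / s for s in true_activity.spacing]
        values = gaussian_filter(values, sigma_vox, mode="reflect", truncate=6.0)
    values = values * counts_scale
    if noise:
        rng = np.random.default_rng(seed)
        values = rng.poisson(values).astype(float)
    return true_activity.with_values(values)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges for a cohort of synthetic patients.

    Defaults reflect a typical post-therapy cohort: 17 patients with 31
    tumors in total, administered activities 1.13-5.21 GBq, lung shunts
    1-20%, and 20 mm FWHM imaging resolution.  All per-phantom parameters
    are drawn uniformly from their ranges using the master seed.
    """

    n: int = 17
    master_seed: int = 7
    administered_range_bq: tuple[float, float] = (1.13e9, 5.21e9)
    ls_range: tuple[float, float] = (0.01, 0.20)
    uptake_ratio_range: tuple[float, float] = (2.0, 6.0)
    tumor_radius_range_mm: tuple[float, float] = (10.0, 30.0)
    total_tumors: int = 31
    max_tumors_per_phantom: int = 3
    fwhm_mm: float = 20.0
    poisson_noise: bool = False
    base: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        if not self.n <= self.total_tumors <= self.n * self.max_tumors_per_phantom:
            raise ValueError(
                "total tumors must allow 1..max_tumors_per_phantom per phantom"
            )


def _tumor_counts(cspec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    counts = np.ones(cspec.n, dtype=int)
    extra = cspec.total_tumors - cspec.n
    while extra > 0:
        candidates = np.flatnonzero(counts < cspec.max_tumors_per_phantom)
        pick = rng.choice(candidates)
        counts[pick] += 1
        extra -= 1
    return counts


def _sample_tumors(
    spec_base: PhantomSpec,
    n_tumors: int,
    cspec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[TumorSpec, ...]:
    """Rejection-sample tumor spheres fully inside the clipped liver."""
    cx, cy, cz = spec_base.liver_center_mm or spec_base.default_liver_center()
    radii = np.asarray(spec_base.liver_radii_mm)
    tumors: list[TumorSpec] = []
    while len(tumors) < n_tumors:
        r = rng.uniform(*cspec.tumor_radius_range_mm)
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(u, u) > 1.0:
            continue
        margin = r + spec_base.spacing_mm  # keep the sphere off the surface
        center = np.array([cx, cy, cz]) + u * np.maximum(radii - margin, 0.0)
        # inside the shrunken ellipsoid and below the interface
        if np.sum((center - [cx, cy, cz]) ** 2 / np.maximum(radii - margin, 1e-9) ** 2) > 1.0:
            continue
        if center[2] + margin > spec_base.interface_z_mm:
            continue
        uptake = rng.uniform(*cspec.uptake_ratio_range)
        tumors.append(TumorSpec(tuple(center), r, uptake))
    return tuple(tumors)


def generate_cohort(cspec: CohortSpec) -> tuple[list[PhantomBundle], list[dict]]:
    """Generate the cohort and a manifest of every drawn parameter."""
    rng = np.random.default_rng(cspec.master_seed)
    counts = _tumor_counts(cspec, rng)
    bundles = []
    manifest = []
    for i in range(cspec.n):
        administered = rng.uniform(*cspec.administered_range_bq)
        ls = rng.uniform(*cspec.ls_range)
        tumors = _sample_tumors(cspec.base, int(counts[i]), cspec, rng)
        spec = PhantomSpec(
            dims=cspec.base.dims,
            spacing_mm=cspec.base.spacing_mm,
            lung_z_start=cspec.base.lung_z_start,
            lung_layers=cspec.base.lung_layers,
            liver_center_mm=cspec.base.liver_center_mm,
            liver_radii_mm=cspec.base.liver_radii_mm,
            tumors=tumors,
            ls=float(ls),
            administered_bq=float(administered),
            fwhm_mm=cspec.fwhm_mm,
            counts_scale=cspec.base.counts_scale,
            poisson_noise=cspec.poisson_noise,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        bundles.append(generate_phantom(spec))
        manifest.append(asdict(spec))
    return bundles, manifest
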
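"""VOI statistics, DVHs, interface-exclusion remainders, and sensitivity fits.

Reported quantities follow radioembolization dosimetry practice: mean
absorbed dose and cumulative dose-volume histograms over the tumor,
non-tumoral liver (NL = liver minus tumors), and right lung (RL) volumes of
interest.  To quantify how sensitive organ mean doses are to segmentation
near the liver-lung interface, remainder VOIs exclude all voxels within a
margin (1-3 cm) of the interface, and the original mean doses are regressed
on the remainder mean doses across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .grid import VoxelGrid
from .engines import (
    DoseMap,
    activity_to_disintegrations,
    counts_to_activity,
    dose_ld,
    dose_rt,
    dose_sk,
    dose_skd,
)
from .kernel import DosePointKernel, VoxelKernel, build_voxel_kernel, load_dpk

__all__ = [
    "DVH",
    "RemainderMasks",
    "SensitivityFit",
    "CohortResult",
    "mean_dose",
    "dvh",
    "interface_exclusion",
    "sensitivity_fit",
    "segment_lung_by_threshold",
    "analyze_cohort",
]


def _mask_array(mask: VoxelGrid | np.ndarray) -> np.ndarray:
    arr = mask.values if isinstance(mask, VoxelGrid) else mask
    return np.asarray(arr).astype(bool)


def _dose_array(d: DoseMap | VoxelGrid) -> np.ndarray:
    return (d.grid if isinstance(d, DoseMap) else d).values


def mean_dose(d: DoseMap | VoxelGrid, mask: VoxelGrid | np.ndarray) -> float:
    """Arithmetic mean absorbed dose (Gy) over the masked voxels."""
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("empty mask")
    return float(_dose_array(d)[m].mean())


@dataclass
class DVH:
    """Cumulative dose-volume histogram: fraction of the VOI >= dose.

    ``fraction[i]`` is the volume fraction receiving at least ``edges[i]``
    Gy; it starts at 1 at 0 Gy, is non-increasing, and reaches 0 above the
    maximum dose.
    """

    edges: np.ndarray
    fraction: np.ndarray

    def mean_dose(self) -> float:
        """Mean dose recovered as the integral of the cumulative DVH."""
        width = np.diff(self.edges, append=2 * self.edges[-1] - self.edges[-2])
        return float((self.fraction * width).sum())

    def volume_fraction_at(self, dose_gy: float) -> float:
        idx = np.searchsorted(self.edges, dose_gy, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.fraction[idx])


def dvh(
    d: DoseMap | VoxelGrid, mask: VoxelGrid | np.ndarray, bin_width: float = 0.5
) -> DVH:
    """Cumulative DVH of the masked doses with the given bin width (Gy)."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    m = _mask_array(mask)
    if not m.any():
        raise ValueError("empty mask")
    doses = _dose_array(d)[m]
    n_bins = int(np.floor(doses.max() / bin_width)) + 2
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(doses, bins=edges)
    below = np.concatenate([[0], np.cumsum(counts)])[:-1]
    fraction = 1.0 - below / doses.size
    return DVH(edges=edges[:-1], fraction=fraction)


@dataclass
class RemainderMasks:
    """Remainder and excluded VOIs for one interface-exclusion margin."""

    margin_mm: float
    remainder_liver: np.ndarray
    remainder_lung: np.ndarray
    excluded_liver: np.ndarray
    excluded_lung: np.ndarray
    n_interface_faces: int


def interface_exclusion(
    liver_mask: VoxelGrid | np.ndarray,
    lung_mask: VoxelGrid | np.ndarray,
    margin_mm: float,
    spacing: tuple[float, float, float] | None = None,
) -> RemainderMasks:
    """Exclude voxels within ``margin_mm`` of the liver-lung interface.

    The interface surface is the set of voxel faces where the liver and
    lung masks are 6-adjacent; a voxel is excluded when its center lies
    within the margin (Euclidean distance to the nearest face center).
    Returns remainder and excluded masks for both organs.
    """
    if spacing is None:
        if not isinstance(liver_mask, VoxelGrid):
            raise ValueError("spacing required when masks are plain arrays")
        spacing = liver_mask.spacing
    liver = _mask_array(liver_mask)
    lung = _mask_array(lung_mask)
    if liver.shape != lung.shape:
        raise ValueError("masks must share one grid")
    if np.any(liver & lung):
        raise ValueError("liver and lung masks overlap")
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")

    sp = np.asarray(spacing, dtype=float)
    faces = []
    for axis in range(3):
        for a, b in ((liver, lung), (lung, liver)):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(0, -1)
            hi[axis] = slice(1, None)
            adj = a[tuple(lo)] & b[tuple(hi)]
            idx = np.argwhere(adj).astype(float)
            if idx.size:
                centers = idx * sp  # center of the lower voxel
                centers[:, axis] += sp[axis] / 2.0  # shift onto the shared face
                faces.append(centers)
    if not faces:
        import warnings

        warnings.warn("no liver-lung adjacency found; nothing excluded", stacklevel=2)
        return RemainderMasks(
            margin_mm=margin_mm,
            remainder_liver=liver.copy(),
            remainder_lung=lung.copy(),
            excluded_liver=np.zeros_like(liver),
            excluded_lung=np.zeros_like(lung),
            n_interface_faces=0,
        )
    face_pts = np.concatenate(faces, axis=0)
    tree = cKDTree(face_pts)

    organ = liver | lung
    pts = np.argwhere(organ) * sp
    dist, _ = tree.query(pts, workers=-1)
    near = np.zeros_like(organ)
    near[tuple(np.argwhere(organ).T)] = dist <= margin_mm
    return RemainderMasks(
        margin_mm=margin_mm,
        remainder_liver=liver & ~near,
        remainder_lung=lung & ~near,
        excluded_liver=liver & near,
        excluded_lung=lung & near,
        n_interface_faces=len(face_pts),
    )


@dataclass
class SensitivityFit:
    """OLS fit of original VOI mean doses on remainder VOI mean doses."""

    slope: float
    intercept: float
    r_squared: float
    mean_percent_change: float
    n: int
    margin_mm: float | None = None


def sensitivity_fit(
    originals: np.ndarray,
    remainders: np.ndarray,
    margin_mm: float | None = None,
) -> SensitivityFit:
    """Regress original mean doses (y) on remainder mean doses (x).

    Also reports the cohort-mean percent change of the remainder relative
    to the original mean dose.
    """
    y = np.asarray(originals, dtype=float)
    x = np.asarray(remainders, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("need two equal-length samples of at least 2 values")
    if np.ptp(x) == 0:
        raise ValueError("remainder doses have zero variance; fit undefined")
    fit = linregress(x, y)
    change = float((100.0 * (x - y) / y).mean())
    return SensitivityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mean_percent_change=change,
        n=y.size,
        margin_mm=margin_mm,
    )


def segment_lung_by_threshold(
    density: VoxelGrid,
    seed_point: tuple[int, int, int],
    threshold: float = 0.70,
) -> np.ndarray:
    """Region-grow a lung mask: connected low-density component of the seed."""
    below = density.values <= threshold
    if not below[tuple(seed_point)]:
        raise ValueError(
            f"seed density {density.values[tuple(seed_point)]:.3f} g/cc is above "
            f"the threshold {threshold} g/cc"
        )
    labels, _ = ndimage.label(below)
    return labels == labels[tuple(seed_point)]


@dataclass
class CohortResult:
    """Per-phantom VOI mean doses and interface-sensitivity summaries.

    ``voi_means[i][voi][engine]`` is the mean dose (Gy) of phantom i;
    ``remainder_means[i][margin][voi][engine]`` the mean dose of the
    remainder VOI at the given exclusion margin (mm).
    """

    voi_means: list[dict[str, dict[str, float]]]
    remainder_means: list[dict[float, dict[str, dict[str, float]]]]
    margins_mm: tuple[float, ...]
    engines: tuple[str, ...]
    reference_engine: str = "RT"

    def max_engine_deviation_pct(
        self,
        vois: tuple[str, ...] = ("tumors", "nl"),
        engines: tuple[str, ...] | None = None,
    ) -> float:
        """Worst |mean - reference|/reference (%) over phantoms/VOIs/engines."""
        engines = engines or tuple(
            e for e in self.engines if e != self.reference_engine
        )
        worst = 0.0
        for means in self.voi_means:
            for voi in vois:
                if voi not in means:
                    continue
                ref = means[voi][self.reference_engine]
                for e in engines:
                    worst = max(worst, abs(means[voi][e] - ref) / ref * 100.0)
        return worst

    def cohort_remainder_means(
        self, voi: str, engine: str | None = None
    ) -> dict[float, float]:
        """Cohort-averaged remainder mean dose per exclusion margin."""
        engine = engine or self.reference_engine
        return {
            m: float(
                np.mean([rm[m][voi][engine] for rm in self.remainder_means])
            )
            for m in self.margins_mm
        }

    def sensitivity(
        self, margin_mm: float, voi: str, engine: str | None = None
    ) -> SensitivityFit:
        """Original-vs-remainder OLS fit across the cohort for one margin."""
        engine = engine or self.reference_engine
        originals = np.array([vm[voi][engine] for vm in self.voi_means])
        remainders = np.array(
            [rm[margin_mm][voi][engine] for rm in self.remainder_means]
        )
        return sensitivity_fit(originals, remainders, margin_mm=margin_mm)


def analyze_cohort(
    bundles,
    dpk: DosePointKernel | None = None,
    kernel: VoxelKernel | None = None,
    margins_mm: tuple[float, ...] = (10.0, 20.0, 30.0),
    engines: tuple[str, ...] = ("LD", "SK", "SKD", "RT"),
) -> CohortResult:
    """Run the full dosimetry chain and VOI analysis over a phantom cohort.

    For each phantom the simulated counts are self-calibrated to the
    administered activity, converted to disintegrations, and fed to the
    requested dose engines; mean doses are collected for the tumor, NL,
    RL, and total-liver VOIs and for their interface-exclusion remainders.
    The transport engine is evaluated only on the analyzed VOI voxels.
    """
    dpk = dpk or load_dpk()
    if kernel is None and any(e in ("SK", "SKD") for e in engines):
        kernel = build_voxel_kernel(dpk, voxel_mm=bundles[0].density.spacing[0])

    voi_means = []
    remainder_means = []
    for bundle in bundles:
        activity = counts_to_activity(bundle.counts, bundle.administered_bq)
        n = activity_to_disintegrations(activity)
        rho = bundle.density
        liver = bundle.masks["liver"]
        rl = bundle.masks["rl"]
        target = liver | rl

        doses: dict[str, DoseMap] = {}
        if "LD" in engines:
            doses["LD"] = dose_ld(n, rho)
        if "SK" in engines:
            doses["SK"] = dose_sk(n, kernel)
        if "SKD" in engines:
            doses["SKD"] = dose_skd(n, kernel, rho)
        if "RT" in engines:
            doses["RT"] = dose_rt(n, rho, dpk, target_mask=target)

        vois = {"liver": liver, "nl": bundle.masks["nl"], "rl": rl}
        if bundle.masks["tumors"].any():
            vois["tumors"] = bundle.masks["tumors"]
        voi_means.append(
            {
                name: {e: mean_dose(d, m) for e, d in doses.items()}
                for name, m in vois.items()
            }
        )

        per_margin: dict[float, dict[str, dict[str, float]]] = {}
        for margin in margins_mm:
            rem = interface_exclusion(
                bundle.density.with_values(liver),
                bundle.density.with_values(rl),
                margin,
            )
            rem_vois = {
                "liver": rem.remainder_liver,
                "nl": rem.remainder_liver & bundle.masks["nl"],
                "rl": rem.remainder_lung,
            }
            per_margin[margin] = {
                name: {e: mean_dose(d, m) for e, d in doses.items()}
                for name, m in rem_vois.items()
                if m.any()
            }
        remainder_means.append(per_margin)

    return CohortResult(
        voi_means=voi_means,
        remainder_means=remainder_means,
        margins_mm=tuple(margins_mm),
        engines=tuple(engines),
    )
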
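"""HU-threshold liver volumetry on 3D CT grids.

Volumes are scalar voxel grids in Hounsfield units (HU) with isotropic
voxel pitch.  Segmentation is a closed HU window, optionally restricted to
the largest 26-connected component ("3D isocontour" behaviour); VOI
statistics are cubic volume-of-interest mean/SD with an optional vessel
exclusion mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

HU_MIN = -1000.0
HU_MAX = 1000.0

#: 3D binary structures for 6-, 18- and 26-connectivity.
_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class CTVolume:
    """A 3D attenuation grid in HU with isotropic voxel pitch (mm)."""

    voxels: np.ndarray
    pitch: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        if not self.pitch > 0:
            raise ValueError(f"voxel pitch must be > 0, got {self.pitch}")
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            warnings.warn(
                f"voxel values [{lo:.1f}, {hi:.1f}] exceed the HU scale "
                f"[{HU_MIN:.0f}, {HU_MAX:.0f}]",
                stacklevel=2,
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.pitch) ** 3

    def world_position(self, index: Sequence[float]) -> np.ndarray:
        """World position (mm) of a voxel index, voxel-centre convention."""
        return np.asarray(self.origin) + (np.asarray(index, float) + 0.5) * self.pitch


@dataclass
class VOI:
    """Cubic volume of interest, default 8 mm^3 (side 2 mm)."""

    center: tuple[int, int, int]
    side_mm: float = 2.0
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.side_mm > 0:
            raise ValueError("VOI side must be > 0")

    def slices(self, volume: CTVolume) -> tuple[slice, slice, slice]:
        """Index slices of the VOI cube; raises if it leaves the grid."""
        n = int(round(self.side_mm / volume.pitch))
        if n < 1:
            raise ValueError("VOI smaller than one voxel")
        out = []
        for ax, c in enumerate(self.center):
            lo = int(c) - n // 2
            hi = lo + n
            if lo < 0 or hi > volume.voxels.shape[ax]:
                raise ValueError(
                    f"VOI [{lo}, {hi}) exceeds grid extent "
                    f"{volume.voxels.shape[ax]} on axis {ax}"
                )
            out.append(slice(lo, hi))
        return tuple(out)


@dataclass
class SegmentationResult:
    """Binary mask plus derived volume and attenuation summaries.

    ``mean_hu`` is NaN (and ``empty`` is True) for an empty mask — never 0.
    """

    mask: np.ndarray
    lower_hu: float
    upper_hu: float
    volume_cm3: float
    mean_hu: float
    n_voxels: int
    component_policy: str = "all-voxels"

    @property
    def empty(self) -> bool:
        return self.n_voxels == 0


def voi_stats(volume: CTVolume, voi: VOI) -> tuple[float, float, int]:
    """Mean and SD of HU over a cubic VOI, after vessel exclusion.

    Returns ``(mean_hu, sd_hu, n_voxels)``; SD uses the n-1 denominator and
    is NaN for a single voxel.  Raises if no voxel survives the exclusion
    mask.
    """
    sl = voi.slices(volume)
    cube = volume.voxels[sl]
    if voi.exclusion_mask is not None:
        excl = np.asarray(voi.exclusion_mask, bool)
        if excl.shape != volume.voxels.shape:
            raise ValueError("exclusion mask shape must match the volume")
        keep = ~excl[sl]
        cube = cube[keep]
    cube = np.asarray(cube, float).ravel()
    if cube.size == 0:
        raise ValueError("VOI empty after exclusion mask")
    sd = float(np.std(cube, ddof=1)) if cube.size > 1 else float("nan")
    return float(np.mean(cube)), sd, int(cube.size)


def largest_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Largest connected component of a binary mask (default 26-connected)."""
    try:
        structure = _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    return labels == int(np.argmax(counts))


def threshold_segment(
    volume: CTVolume,
    lower_hu: float,
    upper_hu: float,
    component_policy: str = "all-voxels",
    connectivity: int = 26,
) -> SegmentationResult:
    """Segment voxels with ``lower_hu <= HU <= upper_hu``.

    ``component_policy`` is ``"all-voxels"`` or ``"largest-component"``
    (keep the largest 26-connected component, connectivity configurable).
    """
    if not lower_hu < upper_hu:
        raise ValueError(f"need lower_hu < upper_hu, got [{lower_hu}, {upper_hu}]")
    if component_policy not in ("all-voxels", "largest-component"):
        raise ValueError(f"unknown component_policy {component_policy!r}")
    v = volume.voxels
    mask = (v >= lower_hu) & (v <= upper_hu)
    if component_policy == "largest-component":
        mask = largest_component(mask, connectivity=connectivity)
    n = int(mask.sum())
    volume_cm3 = n * volume.voxel_volume_mm3 / 1000.0
    mean_hu = float(np.mean(v[mask])) if n else float("nan")
    return SegmentationResult(
        mask=mask,
        lower_hu=float(lower_hu),
        upper_hu=float(upper_hu),
        volume_cm3=volume_cm3,
        mean_hu=mean_hu,
        n_voxels=n,
        component_policy=component_policy,
    )


def threshold_sweep(
    volume: CTVolume,
    lower_list: Iterable[float] = (0.0, 50.0, 100.0, 120.0),
    upper_hu: float = HU_MAX,
    component_policy: str = "all-voxels",
    connectivity: int = 26,
) -> tuple[list[SegmentationResult], dict]:
    """Segment once per ascending lower bound with a fixed open upper bound.

    Returns the per-window results and a monotonicity report: volumes must be
    non-increasing and mean HU non-decreasing as the lower bound rises.
    """
    lowers = [float(x) for x in lower_list]
    if lowers != sorted(lowers):
        raise ValueError("lower_list must be ascending")
    results = [
        threshold_segment(volume, lo, upper_hu, component_policy, connectivity)
        for lo in lowers
    ]
    vols = [r.volume_cm3 for r in results]
    means = [r.mean_hu for r in results]
    nonempty = [m for m in means if np.isfinite(m)]
    report = {
        "volumes_non_increasing": all(a >= b for a, b in zip(vols, vols[1:])),
        "mean_hu_non_decreasing": all(
            a <= b for a, b in zip(nonempty, nonempty[1:])
        ),
    }
    return results, report


def segmented_fraction(seg: SegmentationResult, total_mask: np.ndarray) -> float:
    """Percent of ``total_mask`` voxels captured by the segmentation."""
    total = int(np.asarray(total_mask, bool).sum())
    if total == 0:
        raise ValueError("total mask is empty")
    return 100.0 * seg.n_voxels / total
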
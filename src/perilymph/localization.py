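"""Cell localization relative to vessels.

Inside/outside classification with volume-normalized counts, per-cell
distances to the vessel, zone-wise relative distributions, and the
Golgi-high vs Golgi-low intracellular chemokine intensity ratio.

A cell is "inside" iff the voxel containing its centroid is mask
foreground; the centroid is mapped to the nearest voxel center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .geometry import DistanceMap, VesselScene, ZoneMap, mask_volume

__all__ = [
    "CellRecord",
    "InOutResult",
    "ZoneDistribution",
    "GolgiRatioResult",
    "classify_in_out",
    "distance_to_vessel",
    "zone_distribution",
    "golgi_ratio",
]


@dataclass
class CellRecord:
    """A single cell centroid in µm, with optional synthetic ground truth."""

    id: str
    x: float
    y: float
    z: float | None = None
    label: str = ""
    true_inside: bool | None = None
    true_zone: int | None = None

    @property
    def ndim(self) -> int:
        return 2 if self.z is None else 3

    def coords(self) -> tuple[float, ...]:
        """Centroid in array-axis order: (y, x) or (z, y, x)."""
        if self.z is None:
            return (self.y, self.x)
        return (self.z, self.y, self.x)


@dataclass
class InOutResult:
    n_inside: int
    n_outside: int
    vessel_volume: float
    inside_density: float
    in_out_ratio: float | None

    @property
    def n_total(self) -> int:
        return self.n_inside + self.n_outside


@dataclass
class ZoneDistribution:
    counts: dict[int, int]
    fractions: dict[int, float] | None
    edges: tuple[float, ...]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GolgiRatioResult:
    mfi_high: float
    mfi_low: float
    ratio: float | None
    threshold: float


def _centroid_voxel(
    cell: CellRecord, shape: tuple[int, ...], spacing: Sequence[float]
) -> tuple[int, ...]:
    coords = cell.coords()
    if len(coords) != len(shape):
        raise ValidationError(
            f"cell {cell.id}: {len(coords)}D centroid on a {len(shape)}D grid"
        )
    idx = tuple(int(np.rint(c / s)) for c, s in zip(coords, spacing))
    for ax, (i, n) in enumerate(zip(idx, shape)):
        if i < 0 or i >= n:
            raise ValidationError(
                f"cell {cell.id}: centroid {coords} maps to voxel {idx}, "
                f"outside grid of shape {shape} (axis {ax})"
            )
    return idx


def classify_in_out(cells: Sequence[CellRecord], scene: VesselScene) -> InOutResult:
    """Count cells inside vs outside the vessel mask, volume-normalized.

    ``inside_density`` is ``n_inside / mask_volume`` (cells per µm³, or per
    µm² on 2D grids); the in/out ratio is ``None`` when no cell is outside.
    """
    if not scene.mask.any():
        raise ValidationError("cannot classify against an empty vessel mask")
    n_in = 0
    for cell in cells:
        if scene.mask[_centroid_voxel(cell, scene.shape, scene.spacing)]:
            n_in += 1
    n_out = len(cells) - n_in
    vol = mask_volume(scene.mask, scene.spacing)
    return InOutResult(
        n_inside=n_in,
        n_outside=n_out,
        vessel_volume=vol,
        inside_density=n_in / vol,
        in_out_ratio=(n_in / n_out) if n_out > 0 else None,
    )


def distance_to_vessel(
    cells: Sequence[CellRecord],
    dmap: DistanceMap,
    mean_vessel_radius: float | None = None,
) -> np.ndarray:
    """Distance (µm) of each cell centroid's voxel from the vessel mask.

    Inside cells read 0. If ``mean_vessel_radius`` is given, the
    surface-style distance ``max(d - radius, 0)`` is returned instead
    (centroid distance corrected by a configured mean vessel radius).
    """
    out = np.empty(len(cells), dtype=float)
    for i, cell in enumerate(cells):
        out[i] = dmap.values[_centroid_voxel(cell, dmap.values.shape, dmap.spacing)]
    if mean_vessel_radius is not None:
        out = np.maximum(out - float(mean_vessel_radius), 0.0)
    return out


def distance_summary(distances: np.ndarray) -> dict[str, float]:
    """Mean ± s.e.m. of a group of per-cell distances."""
    d = np.asarray(distances, dtype=float)
    n = d.size
    sem = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {"mean": float(d.mean()), "sem": sem, "n": n}


def zone_distribution(
    cells: Sequence[CellRecord], zone_map: ZoneMap, spacing: Sequence[float]
) -> ZoneDistribution:
    """Per-zone cell counts and fractions by the centroid voxel's zone label.

    All labels present in the zone map are reported (zero counts included);
    with zero cells the fractions are undefined (``None``).
    """
    counts = {int(k): 0 for k in np.unique(zone_map.labels)}
    for cell in cells:
        lab = int(zone_map.labels[_centroid_voxel(cell, zone_map.labels.shape, spacing)])
        counts[lab] = counts.get(lab, 0) + 1
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()} if total > 0 else None
    return ZoneDistribution(counts=counts, fractions=fractions, edges=zone_map.edges)


def golgi_ratio(
    ccl21_image: np.ndarray,
    lyve1_mask: np.ndarray,
    golph4_image: np.ndarray,
    isotype_mfi: float = 0.0,
    quantile: float = 0.75,
) -> GolgiRatioResult:
    """Chemokine MFI in Golgi-high vs Golgi-low regions of the vessel mask.

    Within ``lyve1_mask``, pixels at or above the ``quantile`` of the Golgi
    marker intensity are "high", the rest "low". Reported MFIs are
    isotype-subtracted (clamped at 0); the ratio is ``None`` when either
    region is empty or the low-region MFI is 0.
    """
    ccl21 = np.asarray(ccl21_image, dtype=float)
    golgi = np.asarray(golph4_image, dtype=float)
    m = np.asarray(lyve1_mask, dtype=bool)
    if ccl21.shape != m.shape or golgi.shape != m.shape:
        raise ValidationError("images and mask must share one shape")
    if not m.any():
        raise ValidationError("empty LYVE-1 mask")
    if not 0.0 < quantile < 1.0:
        raise ValidationError("quantile must lie in (0, 1)")
    thr = float(np.quantile(golgi[m], quantile))
    high = m & (golgi >= thr)
    low = m & (golgi < thr)
    if not high.any() or not low.any():
        return GolgiRatioResult(
            mfi_high=float("nan"), mfi_low=float("nan"), ratio=None, threshold=thr
        )
    mfi_high = max(float(ccl21[high].mean()) - isotype_mfi, 0.0)
    mfi_low = max(float(ccl21[low].mean()) - isotype_mfi, 0.0)
    ratio = (mfi_high / mfi_low) if mfi_low > 0 else None
    return GolgiRatioResult(
        mfi_high=mfi_high, mfi_low=mfi_low, ratio=ratio, threshold=thr
    )
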
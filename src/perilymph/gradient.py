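"""Distance-resolved fluorescence profiling around vessel masks.

The pipeline is: maximum-intensity projection of the stack, per-pixel
distance from the vessel mask, rounding of distances to integer µm bins,
per-bin intensity averaging, replicate averaging, and day-referenced
normalization of a day/night pair of replicate sets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import DistanceMap

__all__ = [
    "DistanceProfile",
    "ReplicateProfileSet",
    "max_intensity_projection",
    "distance_profile",
    "average_profiles",
    "normalize_group",
    "subtract_isotype",
]


@dataclass
class DistanceProfile:
    """Distance-binned mean fluorescence intensity.

    ``bin_centers`` are integer-rounded distances in µm (strictly
    increasing); ``n_voxels`` counts the pixels contributing to each bin.
    ``n_sources`` is set by :func:`average_profiles` and counts how many
    member profiles contributed to each bin.
    """

    bin_centers: np.ndarray
    mean_intensity: np.ndarray
    n_voxels: np.ndarray
    source: str = ""
    time_label: float | None = None
    n_sources: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=np.int64)
        if not (
            len(self.bin_centers) == len(self.mean_intensity) == len(self.n_voxels)
        ):
            raise ValidationError("profile arrays must have equal length")
        if self.bin_centers.size and np.any(np.diff(self.bin_centers) <= 0):
            raise ValidationError("bin centers must be strictly increasing")
        if np.any(self.n_voxels < 1):
            raise ValidationError("every reported bin needs n_voxels >= 1")

    def __len__(self) -> int:
        return len(self.bin_centers)

    def scaled(self, factor: float) -> "DistanceProfile":
        out = copy.copy(self)
        out.mean_intensity = self.mean_intensity * factor
        return out

    def peak(self) -> float:
        """Maximum per-bin mean intensity."""
        return float(self.mean_intensity.max())


@dataclass
class ReplicateProfileSet:
    """Profiles from one group (e.g. one clock time), plus bookkeeping."""

    profiles: list[DistanceProfile]
    group: str = ""
    time_label: float | None = None
    normalization: float | None = None
    isotype_profile: DistanceProfile | None = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("a ReplicateProfileSet needs >=1 profile")
        if self.normalization is not None and self.normalization <= 0:
            raise ValidationError("normalization constant must be positive")

    def mean_profile(self) -> DistanceProfile:
        return average_profiles(self.profiles)


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading (z) axis of a 3D stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValidationError("expected a 3D stack with >=1 z-plane")
    return stack.max(axis=0)


def _round_half_away(d: np.ndarray) -> np.ndarray:
    # distances are non-negative; round-half-away-from-zero == floor(d + 0.5)
    return np.floor(d + 0.5)


def distance_profile(
    image: np.ndarray,
    dmap: DistanceMap,
    max_distance: float = 100.0,
    source: str = "",
    time_label: float | None = None,
) -> DistanceProfile:
    """Mean intensity as a function of rounded distance from the vessel.

    Each off-vessel pixel is assigned to the integer-µm bin
    ``round(distance)`` (half away from zero); on-vessel pixels (distance 0)
    are excluded, bins whose center exceeds ``max_distance`` are discarded,
    and empty bins are omitted.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != dmap.values.shape:
        raise ValidationError(
            f"image shape {image.shape} != distance map shape {dmap.values.shape}"
        )
    if max_distance <= 0:
        raise ValidationError("max_distance must be positive")
    off = ~dmap.on_vessel
    bins = _round_half_away(dmap.values[off])
    vals = image[off]
    keep = bins <= max_distance
    bins, vals = bins[keep], vals[keep]
    if bins.size == 0:
        raise ValidationError("no off-vessel pixels within max_distance")
    centers, inverse = np.unique(bins, return_inverse=True)
    sums = np.bincount(inverse, weights=vals)
    counts = np.bincount(inverse)
    return DistanceProfile(
        bin_centers=centers,
        mean_intensity=sums / counts,
        n_voxels=counts,
        source=source,
        time_label=time_label,
    )


def average_profiles(profiles: list[DistanceProfile]) -> DistanceProfile:
    """Unweighted per-bin mean across profiles (fields of view count equally).

    Bins missing in some profiles are averaged over the profiles that
    contain them; the contributing count is reported in ``n_sources``.
    """
    if not profiles:
        raise ValidationError("cannot average an empty list of profiles")
    all_bins = np.unique(np.concatenate([p.bin_centers for p in profiles]))
    sums = np.zeros(all_bins.size)
    nsrc = np.zeros(all_bins.size, dtype=np.int64)
    nvox = np.zeros(all_bins.size, dtype=np.int64)
    for p in profiles:
        pos = np.searchsorted(all_bins, p.bin_centers)
        sums[pos] += p.mean_intensity
        nsrc[pos] += 1
        nvox[pos] += p.n_voxels
    labels = sorted({p.time_label for p in profiles if p.time_label is not None})
    return DistanceProfile(
        bin_centers=all_bins,
        mean_intensity=sums / nsrc,
        n_voxels=nvox,
        source="mean(%d profiles)" % len(profiles),
        time_label=labels[0] if len(labels) == 1 else None,
        n_sources=nsrc,
    )


def normalize_group(
    day: ReplicateProfileSet, night: ReplicateProfileSet
) -> tuple[ReplicateProfileSet, ReplicateProfileSet]:
    """Scale both sets by the peak of the day set's across-replicate mean.

    Every profile in both sets is divided by the maximum over bins of the
    day set's per-bin mean profile, so the normalized day mean attains a
    maximum of exactly 1.0.
    """
    c = day.mean_profile().peak()
    if not np.isfinite(c) or c <= 0:
        raise ValidationError(f"day-set peak must be positive, got {c}")

    def _scale(s: ReplicateProfileSet) -> ReplicateProfileSet:
        return ReplicateProfileSet(
            profiles=[p.scaled(1.0 / c) for p in s.profiles],
            group=s.group,
            time_label=s.time_label,
            normalization=c,
            isotype_profile=s.isotype_profile,
        )

    return _scale(day), _scale(night)


def subtract_isotype(
    profile: DistanceProfile, isotype_profile: DistanceProfile, clamp: bool = True
) -> DistanceProfile:
    """Per-bin background subtraction on the shared bins.

    Negative differences are clamped at 0 unless ``clamp=False``.
    """
    common, ia, ib = np.intersect1d(
        profile.bin_centers, isotype_profile.bin_centers, return_indices=True
    )
    if common.size == 0:
        raise ValidationError("profile and isotype share no distance bins")
    diff = profile.mean_intensity[ia] - isotype_profile.mean_intensity[ib]
    if clamp:
        diff = np.maximum(diff, 0.0)
    return DistanceProfile(
        bin_centers=common,
        mean_intensity=diff,
        n_voxels=profile.n_voxels[ia],
        source=profile.source,
        time_label=profile.time_label,
    )
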
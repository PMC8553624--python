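"""Synthetic scene, cell, series, track and bioluminescence generators.

Every generator is a pure function of its spec and a seed, and emits
ground truth next to the data so every analysis stage can be validated
without real microscopy. The peri-vessel chemokine field is modelled as an
exponential decay from the vessel, ``I(d, t) = I0(t)·exp(-d/λ) + b``, with
``I0(t)`` following a 24-h cosine (mesor/amplitude/acrophase); the decay
form is a simulator choice, not a physical claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .geometry import DistanceMap, VesselScene, distance_transform, make_zone_map
from .localization import CellRecord
from .rhythm import LumiSeries, RhythmSeries
from .tracks import Track

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "CellPlacementSpec",
    "TrackSpec",
    "gen_scene",
    "gen_cells",
    "gen_rhythm_series",
    "gen_tracks",
    "gen_lumi",
]


@dataclass
class SceneSpec:
    """Geometry + gradient + circadian modulation of a synthetic scene.

    ``segments`` are capsules: ((p0, p1), radius) with endpoints in µm,
    array-axis order. Intensity peak I0(t) = mesor + amplitude·cos(2π(t −
    acrophase)/24).
    """

    shape: tuple[int, ...] = (30, 256, 256)
    spacing: tuple[float, ...] = (1.0, 0.5, 0.5)
    segments: tuple[tuple[tuple[float, ...], tuple[float, ...], float], ...] = ()
    radius: float = 15.0  # used by the default centered capsule when segments=()
    decay_length: float = 20.0  # λ, µm
    baseline: float = 10.0  # b
    noise_sigma: float = 0.0  # Gaussian σ on intensity
    mesor: float = 100.0  # M of I0(t)
    amplitude: float = 0.0  # A of I0(t)
    acrophase: float = 7.0  # φ, hours
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.decay_length <= 0:
            raise ValidationError("radius and decay length must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be >= 0")
        if self.amplitude > self.mesor:
            raise ValidationError("amplitude must not exceed mesor (I0 >= 0)")
        if len(self.shape) != len(self.spacing):
            raise ValidationError("shape and spacing dimensionality differ")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")

    def resolved_segments(self):
        """Default geometry: one gently bent capsule through the grid center."""
        if self.segments:
            return self.segments
        extent = [(n - 1) * s for n, s in zip(self.shape, self.spacing)]

        def clamp(point):
            # keep endpoints at least one radius inside the grid
            return tuple(
                min(max(c, min(self.radius, 0.5 * e)), max(e - self.radius, 0.5 * e))
                for c, e in zip(point, extent)
            )

        if len(self.shape) == 2:
            ey, ex = extent
            a = (0.5 * ey, 0.15 * ex)
            m = (0.62 * ey, 0.5 * ex)
            b = (0.45 * ey, 0.85 * ex)
        else:
            ez, ey, ex = extent
            a = (0.5 * ez, 0.5 * ey, 0.15 * ex)
            m = (0.5 * ez, 0.62 * ey, 0.5 * ex)
            b = (0.5 * ez, 0.45 * ey, 0.85 * ex)
        a, m, b = clamp(a), clamp(m), clamp(b)
        return ((a, m, self.radius), (m, b, self.radius))


@dataclass
class SceneTruth:
    """Generator-side ground truth; analysis stages must never read this."""

    mask: np.ndarray
    distance: np.ndarray  # µm, voxel-center distance to mask
    noiseless: np.ndarray
    peak_intensity: float  # I0 at the generated time
    spec: SceneSpec


def _segment_distance_grid(
    shape: tuple[int, ...],
    spacing: tuple[float, ...],
    p0: Sequence[float],
    p1: Sequence[float],
) -> np.ndarray:
    """Distance of every voxel center to the segment p0-p1 (µm)."""
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(*coords, indexing="ij")
    a = np.asarray(p0, dtype=float)
    b = np.asarray(p1, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        t = np.zeros(shape)
    else:
        t = sum((g - ai) * abi for g, ai, abi in zip(grids, a, ab)) / denom
        t = np.clip(t, 0.0, 1.0)
    sq = np.zeros(shape)
    for g, ai, abi in zip(grids, a, ab):
        sq += (g - (ai + t * abi)) ** 2
    return np.sqrt(sq)


def capsule_mask(spec: SceneSpec) -> np.ndarray:
    """Voxels within radius of any capsule segment."""
    mask = np.zeros(spec.shape, dtype=bool)
    extent = [(n - 1) * s for n, s in zip(spec.shape, spec.spacing)]
    for p0, p1, radius in spec.resolved_segments():
        # the centerline must stay on the grid; the tube may be clipped by it
        for p in (p0, p1):
            for c, e in zip(p, extent):
                if c < -max(spec.spacing) or c > e + max(spec.spacing):
                    raise ValidationError(
                        f"capsule endpoint {p} lies outside the grid extent {extent}"
                    )
        mask |= _segment_distance_grid(spec.shape, spec.spacing, p0, p1) <= radius
    if not mask.any():
        raise ValidationError("capsule geometry produced an empty mask")
    return mask


def peak_intensity_at(spec: SceneSpec, time_label: float | None) -> float:
    if time_label is None:
        return spec.mesor
    return spec.mesor + spec.amplitude * math.cos(
        2.0 * math.pi * (time_label - spec.acrophase) / 24.0
    )


def gen_scene(
    spec: SceneSpec,
    time_label: float | None = None,
    seed: int | None = None,
) -> tuple[VesselScene, SceneTruth]:
    """Render a vessel scene with a peri-vessel chemokine gradient.

    Intensity = I0(t)·exp(-d/λ) + b + noise, clamped at 0, where d is the
    voxel-center distance to the vessel mask. Deterministic for fixed
    (spec, seed); ``seed=None`` uses ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask = capsule_mask(spec)
    dist = distance_transform(mask, spec.spacing).values
    i0 = peak_intensity_at(spec, time_label)
    noiseless = i0 * np.exp(-dist / spec.decay_length) + spec.baseline
    if spec.noise_model == "poisson" and spec.noise_sigma > 0:
        intensity = rng.poisson(np.maximum(noiseless, 0.0)).astype(float)
    elif spec.noise_sigma > 0:
        intensity = np.maximum(
            noiseless + rng.normal(0.0, spec.noise_sigma, size=spec.shape), 0.0
        )
    else:
        intensity = noiseless.copy()
    scene = VesselScene(
        channels={"chemokine": intensity},
        mask=mask,
        spacing=spec.spacing,
        time_label=time_label,
        meta=f"synthetic capsule scene (seed={spec.seed if seed is None else seed})",
    )
    truth = SceneTruth(
        mask=mask, distance=dist, noiseless=noiseless, peak_intensity=i0, spec=spec
    )
    return scene, truth


@dataclass
class CellPlacementSpec:
    """How to scatter cells around (and inside) the vessel."""

    n_cells: int = 50
    inside_fraction: float = 0.2
    density: Callable[[np.ndarray], np.ndarray] | None = None  # ρ(d), outside cells
    zone_edges: tuple[float, ...] | None = None  # for ground-truth zone labels
    min_spacing: float = 0.0  # µm between any two cells
    boundary_margin_voxels: int = 1  # keep cells this many voxels off the boundary
    jitter: float = 0.4  # sub-voxel jitter, fraction of half a voxel
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inside_fraction <= 1.0:
            raise ValidationError("inside_fraction must be in [0, 1]")
        if self.n_cells < 0 or self.min_spacing < 0:
            raise ValidationError("n_cells and min_spacing must be >= 0")
        if not 0.0 <= self.jitter < 1.0:
            raise ValidationError("jitter must be in [0, 1)")


def _record_from_voxel(idx, spacing, rng, jitter, cid, inside, zone) -> CellRecord:
    offs = rng.uniform(-0.5 * jitter, 0.5 * jitter, size=len(idx))
    pos = [(i + o) * s for i, o, s in zip(idx, offs, spacing)]
    if len(pos) == 2:
        yy, xx = pos
        zz = None
    else:
        zz, yy, xx = pos
    return CellRecord(
        id=cid, x=xx, y=yy, z=zz, true_inside=inside, true_zone=zone
    )


def gen_cells(
    spec: CellPlacementSpec,
    scene: VesselScene,
    seed: int | None = None,
) -> list[CellRecord]:
    """Place cells with a distance-dependent density and known ground truth.

    ``round(inside_fraction · n)`` cells are sampled uniformly over interior
    mask voxels (eroded by the boundary margin), the rest over off-vessel
    voxels at least the margin away from the mask, weighted by ρ(distance)
    when a density is given. Minimum spacing is enforced by bounded
    rejection; an unsatisfiable spec raises after the attempt budget.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dmap = distance_transform(scene.mask, scene.spacing)
    zone_map = (
        make_zone_map(dmap, spec.zone_edges) if spec.zone_edges is not None else None
    )

    inner = scene.mask
    if spec.boundary_margin_voxels > 0:
        inner = ndimage.binary_erosion(
            scene.mask, iterations=spec.boundary_margin_voxels
        )
        if not inner.any():
            inner = scene.mask
    inside_pool = np.argwhere(inner)

    margin_um = spec.boundary_margin_voxels * max(scene.spacing)
    outside_sel = dmap.values > margin_um
    outside_pool = np.argwhere(outside_sel)
    if spec.density is not None:
        w = np.asarray(spec.density(dmap.values[outside_sel]), dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("density must be non-negative with positive mass")
        out_p = w / w.sum()
    else:
        out_p = None

    n_in = int(round(spec.inside_fraction * spec.n_cells))
    n_out = spec.n_cells - n_in
    if n_in > 0 and inside_pool.shape[0] == 0:
        raise ValidationError("no interior voxels available for inside cells")
    if n_out > 0 and outside_pool.shape[0] == 0:
        raise ValidationError("no off-vessel voxels available outside the margin")

    cells: list[CellRecord] = []
    placed: list[np.ndarray] = []
    budget = 200 * max(spec.n_cells, 1)
    attempts = 0
    want = [(True, n_in), (False, n_out)]
    for inside, n_want in want:
        pool = inside_pool if inside else outside_pool
        probs = None if inside else out_p
        n_done = 0
        while n_done < n_want:
            attempts += 1
            if attempts > budget:
                raise ValidationError(
                    "could not satisfy cell min_spacing within the attempt budget"
                )
            k = int(rng.choice(pool.shape[0], p=probs))
            idx = tuple(int(v) for v in pool[k])
            zone = int(zone_map.labels[idx]) if zone_map is not None else None
            rec = _record_from_voxel(
                idx,
                scene.spacing,
                rng,
                spec.jitter,
                f"cell_{len(cells):04d}",
                inside,
                zone,
            )
            p = np.asarray(rec.coords())
            if spec.min_spacing > 0 and any(
                np.linalg.norm(p - q) < spec.min_spacing for q in placed
            ):
                continue
            placed.append(p)
            cells.append(rec)
            n_done += 1
    return cells


def gen_rhythm_series(
    mesor: float,
    amplitude: float,
    acrophase: float,
    sigma: float,
    n_per_time: int,
    times: Sequence[float] = (1.0, 7.0, 13.0, 19.0),
    seed: int = 0,
    group_id: str = "",
) -> RhythmSeries:
    """Replicate samples of M + A·cos(2π(t − φ)/24) + N(0, σ²) at clock times."""
    if sigma < 0 or n_per_time < 1:
        raise ValidationError("need sigma >= 0 and n_per_time >= 1")
    rng = np.random.default_rng(seed)
    t = np.repeat(np.asarray(times, dtype=float), n_per_time)
    clean = mesor + amplitude * np.cos(2.0 * np.pi * (t - acrophase) / 24.0)
    values = clean + (rng.normal(0.0, sigma, size=t.size) if sigma > 0 else 0.0)
    reps = np.tile(np.arange(n_per_time), len(times))
    return RhythmSeries(times=t, values=values, replicate_ids=reps, group_id=group_id)


@dataclass
class TrackSpec:
    """Persistent biased random walk parameters."""

    n_tracks: int = 50
    n_steps: int = 30
    speed_mean: float = 0.1  # µm/s
    speed_sd: float = 0.0
    persistence: float = 0.5  # weight on the previous heading, [0, 1]
    bias: float = 0.0  # weight on the bias direction, [0, 1]
    bias_direction: tuple[float, float] = (1.0, 0.0)
    frame_interval: float = 100.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias <= 1.0 or not 0.0 <= self.persistence <= 1.0:
            raise ValidationError("bias and persistence must lie in [0, 1]")
        if self.frame_interval <= 0:
            raise ValidationError("frame interval must be positive")
        if self.n_steps < 1 or self.n_tracks < 0:
            raise ValidationError("need n_steps >= 1 and n_tracks >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def gen_tracks(spec: TrackSpec, seed: int | None = None) -> list[Track]:
    """Correlated random walks with an optional directional bias.

    Each step heading is the normalized mixture
    ``bias·u_bias + (1 − bias)·(persistence·u_prev + (1 − persistence)·u_rand)``,
    so ``bias = 1`` yields perfectly straight, co-oriented tracks. Step
    lengths are speed × frame interval, speeds drawn from a truncated
    normal (point mass when ``speed_sd = 0``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    u_bias = _unit(np.asarray(spec.bias_direction, dtype=float))
    tracks: list[Track] = []
    for i in range(spec.n_tracks):
        theta0 = rng.uniform(0.0, 2.0 * np.pi)
        heading = np.array([np.cos(theta0), np.sin(theta0)])
        pos = np.zeros((spec.n_steps + 1, 2))
        for k in range(spec.n_steps):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            u_rand = np.array([np.cos(theta), np.sin(theta)])
            mix = spec.bias * u_bias + (1.0 - spec.bias) * (
                spec.persistence * heading + (1.0 - spec.persistence) * u_rand
            )
            heading = _unit(mix) if np.linalg.norm(mix) > 0 else u_rand
            speed = spec.speed_mean
            if spec.speed_sd > 0:
                speed = max(rng.normal(spec.speed_mean, spec.speed_sd), 0.0)
            pos[k + 1] = pos[k] + heading * speed * spec.frame_interval
        t = np.arange(spec.n_steps + 1) * spec.frame_interval
        tracks.append(
            Track(
                track_id=f"track_{i:04d}",
                t=t,
                x=pos[:, 0],
                y=pos[:, 1],
                frames=np.arange(1, spec.n_steps + 2),
            )
        )
    return tracks


def gen_lumi(
    baseline: float = 100.0,
    amplitude: float = 20.0,
    period_h: float = 24.0,
    damping_per_h: float = 0.0,
    trend_slope_per_h: float = 0.0,
    sigma: float = 0.0,
    duration_h: float = 96.0,
    dt_min: float = 1.0,
    seed: int = 0,
) -> LumiSeries:
    """Damped rhythmic bioluminescence with a slow linear trend.

    counts(t) = baseline + slope·t + A·exp(−γt)·cos(2πt/period) + noise,
    sampled every ``dt_min`` minutes.
    """
    if duration_h <= 2 * period_h:
        raise ValidationError("duration must exceed two periods")
    if dt_min <= 0 or sigma < 0:
        raise ValidationError("need dt_min > 0 and sigma >= 0")
    rng = np.random.default_rng(seed)
    t_min = np.arange(0.0, duration_h * 60.0 + 0.5 * dt_min, dt_min)
    t_h = t_min / 60.0
    counts = (
        baseline
        + trend_slope_per_h * t_h
        + amplitude * np.exp(-damping_per_h * t_h) * np.cos(2.0 * np.pi * t_h / period_h)
    )
    if sigma > 0:
        counts = counts + rng.normal(0.0, sigma, size=t_min.size)
    return LumiSeries(t_min=t_min, counts=counts)
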
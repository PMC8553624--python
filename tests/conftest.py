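"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
nearest-foreground search is an exhaustive min over foreground voxels, and
point-in-polygon is a crossing-number test with an explicit on-segment
check.
"""

from __future__ import annotations

import numpy as np
import pytest


def brute_force_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Exhaustive min-over-foreground Euclidean distance, voxel centers, µm."""
    mask = np.asarray(mask, bool)
    sp = np.asarray(spacing, float)
    fg = np.argwhere(mask).astype(float)  # (F, ndim)
    coords = np.argwhere(np.ones(mask.shape, bool)).astype(float)  # (V, ndim)
    diff = (coords[:, None, :] - fg[None, :, :]) * sp
    d = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    return d.reshape(mask.shape)


def point_in_polygon(px: float, py: float, verts: np.ndarray, eps: float = 1e-9) -> bool:
    """Crossing-number point-in-polygon with boundary counted as inside."""
    v = np.asarray(verts, float)
    n = len(v)
    # on-boundary check: distance to any closing segment
    for i in range(n):
        ax, ay = v[i]
        bx, by = v[(i + 1) % n]
        abx, aby = bx - ax, by - ay
        denom = abx * abx + aby * aby
        t = 0.0 if denom == 0 else max(0.0, min(1.0, ((px - ax) * abx + (py - ay) * aby) / denom))
        dx, dy = px - (ax + t * abx), py - (ay + t * aby)
        if dx * dx + dy * dy < eps * eps:
            return True
    inside = False
    for i in range(n):
        ax, ay = v[i]
        bx, by = v[(i + 1) % n]
        if (ay > py) != (by > py):
            x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_cross:
                inside = not inside
    return inside


def random_mask(rng: np.random.Generator, shape, n_points: int) -> np.ndarray:
    """Sparse random foreground: n_points voxels set, at least one."""
    mask = np.zeros(shape, dtype=bool)
    flat = rng.choice(mask.size, size=max(n_points, 1), replace=False)
    mask.flat[flat] = True
    return mask


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """A deterministic noiseless 2D capsule scene for geometry/gradient tests."""
    from perilymph import SceneSpec, gen_scene

    spec = SceneSpec(
        shape=(96, 96),
        spacing=(0.5, 0.5),
        radius=6.0,
        decay_length=15.0,
        baseline=5.0,
        noise_sigma=0.0,
        mesor=100.0,
        seed=7,
    )
    return gen_scene(spec, time_label=7.0)
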
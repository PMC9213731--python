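"""Shared fixtures: small grids, voxelized spheres and random blob masks."""

from __future__ import annotations

import numpy as np
import pytest

from adaptqa.grids import BinaryStructure, GridGeometry


def make_geometry(n=24, spacing=2.0):
    return GridGeometry((n, n, n), (spacing,) * 3)


def sphere(geom: GridGeometry, center_mm, r_mm, name="sphere") -> BinaryStructure:
    axes = [
        o + s * np.arange(nn, dtype=float)
        for nn, s, o in zip(geom.shape, geom.spacing_mm, geom.origin_mm)
    ]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij", sparse=True)
    cx, cy, cz = center_mm
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2 <= r_mm**2
    return BinaryStructure(name, geom, mask)


def random_blob(geom: GridGeometry, rng: np.random.Generator, name="blob") -> BinaryStructure:
    """Non-empty random smooth blob mask (thresholded filtered noise)."""
    from scipy import ndimage

    while True:
        noise = ndimage.gaussian_filter(rng.standard_normal(geom.shape), sigma=2.0)
        mask = noise > np.percentile(noise, 85)
        if mask.any() and not mask.all():
            return BinaryStructure(name, geom, mask)


def brute_force_distance_map(structure: BinaryStructure, signed=False) -> np.ndarray:
    """Exhaustive pairwise-minimum oracle for the Euclidean distance map."""
    geom = structure.geometry
    spacing = np.asarray(geom.spacing_mm)
    all_idx = np.argwhere(np.ones(geom.shape, dtype=bool)) * spacing
    inside = np.argwhere(structure.mask) * spacing
    outside = np.argwhere(~structure.mask) * spacing

    def min_dist(points, targets):
        out = np.empty(len(points))
        for i, p in enumerate(points):
            out[i] = np.sqrt(((targets - p) ** 2).sum(axis=1)).min()
        return out

    d_out = min_dist(all_idx, inside).reshape(geom.shape)
    if not signed:
        return d_out
    d_in = min_dist(all_idx, outside).reshape(geom.shape)
    return np.where(structure.mask, -d_in, d_out)


@pytest.fixture
def geom16():
    return make_geometry(16, 2.0)


@pytest.fixture
def geom24():
    return make_geometry(24, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
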
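"""Radiomic descriptors of airway trees and lung volumes.

The descriptors compose the tree model with the persistence core:

* upwards/directional complexity — number of finite bars of the degree-0
  barcode of the depth (height-below-top) filtration of the centerline graph,
  i.e. the number of times a branch changes trajectory to stretch upwards in
  the chosen direction;
* branch-to-branch proximity — total persistence of the degree-1 barcode of
  the alpha filtration on the tree's nodes: each bar (r1, r2) is a loop
  created when virtually thickened branches touch at radius r1 and filled at
  radius r2, so the sum quantifies how strongly branches curve toward one
  another;
* void descriptor — the degree-2 alpha barcode of the point cloud of surface
  voxels (airway luminal surface plus lobe surface), describing how the
  airways fill the cavity of the lobe at a resolution finer than the voxel
  grid permits directly;
* two conventional baselines: the emphysema score (LAA%) and the lumen voxel
  count.

Degenerate trees with fewer than 2 nodes return 0 for all complexity
features rather than erroring, so cohort tables stay total.
"""

from __future__ import annotations

import warnings

import numpy as np

from .alpha import alpha_filtration
from .errors import MissingLabelsError
from .persistence import Barcode, FiltrationFunction, persistence, sublevel_barcode_deg0
from .tree import AirwayTree, ScanMeta, rotate_tree
from .volumes import VoxelVolume, voxel_to_pointcloud

__all__ = [
    "height_function",
    "upwards_complexity",
    "directional_complexity",
    "branch_to_branch_proximity",
    "void_barcode",
    "height_barcode",
    "normalize_by_height",
    "thin_points",
]


def height_function(tree: AirwayTree) -> FiltrationFunction:
    """Depth below the top of the tree's axis-aligned bounding box.

    f(v) = z_max - z(v); the topmost vertex has value 0.  Sliding a
    horizontal plane downwards from the top, the sublevel set at depth h is
    exactly the part of the tree above the plane.
    """
    z = tree.positions[:, 2]
    zmax = float(z.max()) if len(z) else 0.0
    return FiltrationFunction(
        {int(i): zmax - float(zi) for i, zi in zip(tree.ids, z)}
    )


def height_barcode(tree: AirwayTree) -> Barcode:
    """Degree-0 barcode of the depth filtration (units: mm of depth)."""
    return sublevel_barcode_deg0(tree, height_function(tree))


def upwards_complexity(tree: AirwayTree) -> int:
    """Number of upward changes of trajectory of the airways.

    Counted as the finite bars of the depth-filtration degree-0 barcode: each
    finite bar is a component born at a local top of a branch (an upward
    excursion) that later merges into an older component.  The essential bar
    represents the whole tree and is not counted.
    """
    if tree.n_nodes < 2:
        return 0
    bc = height_barcode(tree)
    return len(bc.finite())


def directional_complexity(tree: AirwayTree, angles_deg) -> int:
    """Upwards complexity after rigidly rotating the tree by ``angles_deg``
    (degrees about the fixed X, then Y, then Z axes, right-hand rule)."""
    if tree.n_nodes < 2:
        return 0
    return upwards_complexity(rotate_tree(tree, angles_deg))


def thin_points(points: np.ndarray, max_points: int | None) -> np.ndarray:
    """Deterministically thin an ordered point sequence to ``max_points`` by
    taking evenly spaced indices.  Because centerline nodes are ordered and
    uniformly spaced along branches, this preserves branch geometry at a
    coarser, still uniform, sampling density."""
    if max_points is None or len(points) <= max_points:
        return points
    idx = np.unique(np.round(np.linspace(0, len(points) - 1, max_points)).astype(int))
    return points[idx]


def branch_to_branch_proximity(
    tree: AirwayTree, jitter_seed: int = 0, max_points: int | None = None
) -> float:
    """Sum of r2 - r1 over the degree-1 alpha barcode of the tree's nodes (mm).

    Thickening every node into a ball of growing radius, a loop appears at
    radius r1 when two branches touch and disappears at r2 when the loop is
    filled; the sum of these lifetimes measures branch crowding.

    ``max_points`` optionally thins dense centerlines (see
    :func:`thin_points`) to bound the triangulation size on very large trees.
    """
    pts = np.unique(tree.positions, axis=0)
    if len(pts) < 4:
        warnings.warn("fewer than 4 distinct nodes: no 1-cycles possible")
        return 0.0
    pts = thin_points(tree.positions, max_points)
    cx = alpha_filtration(pts, jitter_seed=jitter_seed)
    bc = persistence(cx, degree=1)
    return bc.capped().total_persistence()


def void_barcode(
    vol: VoxelVolume, jitter_seed: int = 0, max_points: int | None = None
) -> Barcode:
    """Degree-2 alpha barcode of the surface-voxel point cloud (mm radii).

    ``vol`` must be a binary surface_labels volume combining the lobe surface
    with the airway luminal surface.  Each bar is a void enclosed by the
    thickened surfaces; its death is the circumradius of the largest empty
    ball inside the void.
    """
    if vol.kind != "surface_labels":
        raise ValueError("void_barcode expects a surface_labels volume")
    pts = voxel_to_pointcloud(vol)
    if max_points is not None and len(pts) > max_points:
        rng = np.random.default_rng(int(jitter_seed))
        sel = rng.choice(len(pts), size=max_points, replace=False)
        pts = pts[np.sort(sel)]
    cx = alpha_filtration(pts, jitter_seed=jitter_seed)
    return persistence(cx, degree=2)


def normalize_by_height(value: float, meta: ScanMeta) -> float:
    """Divide a descriptor by the participant's body height (per metre)."""
    if meta.body_height is None:
        raise MissingLabelsError(
            f"body height missing for participant {meta.participant_id}"
        )
    return float(value) / float(meta.body_height)
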
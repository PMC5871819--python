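"""Alpha-complex filtrations of 3D point clouds.

The alpha complex of a finite point set is the subcomplex of its Delaunay
triangulation in which every simplex is assigned the smallest radius r such
that the simplex belongs to the union of balls of radius r centred at the
points.  Filtration values are stored in *radius* units (mm), so that, e.g.,
an edge between two points 1 mm apart enters at r = 0.5 mm and the death of a
void equals the circumradius of the largest empty ball inside it.

Assignment of values follows the standard downward propagation over the
Delaunay complex: a top-dimensional simplex takes its circumradius; a lower
simplex takes its own circumradius if it is Gabriel (its smallest
circumscribing ball, centred in its affine hull, contains no opposite vertex
of a coface), otherwise the minimum value over its cofaces.

Voxel-grid point clouds are highly degenerate for Delaunay triangulation
(collinear and cocircular configurations everywhere), so a deterministic
seeded jitter of magnitude 1e-6 times the bounding-box diagonal is always
applied before triangulating; the seed is recorded in provenance.  Point sets
whose affine hull has dimension < 3 (a straight or planar branch) are
triangulated in their own affine dimension.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial import Delaunay

from .errors import DegenerateInputError
from .persistence import FilteredComplex

__all__ = ["alpha_filtration"]

JITTER_SCALE = 1e-6


def _circumradius2(pts: np.ndarray) -> float:
    """Squared radius of the smallest sphere through all vertices of a
    simplex with centre in the simplex's affine hull."""
    v0 = pts[0]
    m = pts[1:] - v0
    if len(m) == 0:
        return 0.0
    b = np.einsum("ij,ij->i", m, m)
    gram = 2.0 * (m @ m.T)
    try:
        y = np.linalg.solve(gram, b)
    except np.linalg.LinAlgError:
        y = np.linalg.lstsq(gram, b, rcond=None)[0]
    c = m.T @ y
    return float(c @ c)


def _circumcenter(pts: np.ndarray) -> np.ndarray:
    v0 = pts[0]
    m = pts[1:] - v0
    b = np.einsum("ij,ij->i", m, m)
    gram = 2.0 * (m @ m.T)
    try:
        y = np.linalg.solve(gram, b)
    except np.linalg.LinAlgError:
        y = np.linalg.lstsq(gram, b, rcond=None)[0]
    return v0 + m.T @ y


def alpha_filtration(points, jitter_seed: int = 0) -> FilteredComplex:
    """Build the alpha-complex filtration of a 3D point cloud.

    Parameters
    ----------
    points : (n, 3) array-like, mm.  Exact duplicates are removed.
    jitter_seed : seed of the deterministic symmetry-breaking jitter.

    Returns
    -------
    FilteredComplex with values in mm (radius units).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise DegenerateInputError("empty point cloud")
    pts = np.unique(pts, axis=0)
    if len(pts) == 1 and np.asarray(points).reshape(-1, 3).shape[0] > 1:
        raise DegenerateInputError("all points identical")

    prov = [f"alpha jitter_seed={int(jitter_seed)} scale={JITTER_SCALE}"]
    if len(pts) == 1:
        return FilteredComplex({(0,): 0.0}, units="mm_radius", provenance=prov)

    bbox_diag = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    rng = np.random.default_rng(int(jitter_seed))
    jit = rng.uniform(-1.0, 1.0, size=pts.shape) * (JITTER_SCALE * bbox_diag)
    pj = pts + jit

    # effective affine dimension (degenerate clouds: straight/planar branches)
    centered = pj - pj.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    # must exceed the jitter magnitude, or a planar cloud would be seen as 3D
    tol = max(bbox_diag * 10 * JITTER_SCALE, 1e-12)
    eff_dim = int(np.sum(svals > tol))
    eff_dim = max(eff_dim, 1)
    eff_dim = min(eff_dim, len(pj) - 1, 3)

    if eff_dim == 1:
        # points on a line: path complex between consecutive points
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        t = centered @ vt[0]
        order = np.argsort(t)
        simplices: dict[tuple[int, ...], float] = {(int(i),): 0.0 for i in range(len(pj))}
        for a, b in zip(order[:-1], order[1:]):
            d = float(np.linalg.norm(pj[a] - pj[b]))
            simplices[tuple(sorted((int(a), int(b))))] = d / 2.0
        return FilteredComplex(simplices, units="mm_radius", provenance=prov)

    if eff_dim == 2:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        coords = centered @ vt[:2].T
    else:
        coords = pj

    tri = Delaunay(coords)
    top = [tuple(sorted(int(v) for v in s)) for s in tri.simplices]

    # enumerate all faces, grouped by dimension
    dims: list[dict[tuple[int, ...], float | None]] = [dict() for _ in range(eff_dim + 1)]
    for s in top:
        dims[eff_dim][s] = None
    for d in range(eff_dim, 0, -1):
        for s in dims[d]:
            for f in itertools.combinations(s, d):
                dims[d - 1].setdefault(f, None)
    for i in range(len(pj)):
        dims[0].setdefault((i,), None)

    # downward value assignment (squared radii), Gabriel test per coface
    for d in range(eff_dim, 0, -1):
        layer = dims[d]
        for s in layer:
            if layer[s] is None:
                layer[s] = _circumradius2(coords[list(s)])
            vs = layer[s]
            for f in itertools.combinations(s, d):
                sub = dims[d - 1]
                if sub[f] is not None:
                    sub[f] = min(sub[f], vs)
                elif d - 1 >= 1:
                    # Gabriel test: opposite vertex inside circumsphere of f?
                    fpts = coords[list(f)]
                    c = _circumcenter(fpts)
                    r2 = float(np.sum((fpts[0] - c) ** 2))
                    (u,) = set(s) - set(f)
                    if float(np.sum((coords[u] - c) ** 2)) < r2:
                        sub[f] = vs
    for v in dims[0]:
        dims[0][v] = 0.0

    simplices = {}
    for layer in dims:
        for s, val in layer.items():
            simplices[s] = float(np.sqrt(max(val, 0.0)))
    # guard monotonicity against round-off
    for d in range(1, eff_dim + 1):
        for s in dims[d]:
            m = max(simplices[f] for f in itertools.combinations(s, d))
            if simplices[s] < m:
                simplices[s] = m
    return FilteredComplex(simplices, units="mm_radius", provenance=prov)
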
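"""Distances between persistence barcodes.

Both metrics are optimal-matching distances on persistence diagrams: every
bar may be matched either to a bar of the other diagram (ground cost: L-inf
distance between the (birth, death) points) or to the diagonal (cost: half
its persistence).

* Bottleneck distance: minimise the maximum matched cost.  Computed exactly
  by a binary search over the finite set of candidate costs with a bipartite
  feasibility matching at each step, so the result satisfies any requested
  relative-error bound (the ``relative_error`` argument, default 1e-4, is
  kept for API compatibility and validated but cannot be violated).
* Wasserstein distance of order q (default 2): minimise the sum of matched
  costs to the power q, then take the q-th root.  Computed exactly as a
  linear assignment on the diagonally-augmented cost matrix.

Essential (infinite) bars must be capped before comparison; see
:meth:`airwaytopo.persistence.Barcode.capped`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .persistence import Barcode, _check_comparable

__all__ = ["bottleneck_distance", "wasserstein_distance", "total_persistence"]


def _finite_bars(b: Barcode) -> np.ndarray:
    if b.n_infinite():
        raise ValueError(
            "barcode has essential bars; cap them (Barcode.capped) before "
            "computing distances"
        )
    return np.asarray(b.bars, dtype=float).reshape(-1, 2)


def _matching_feasible(cost: np.ndarray, diag_a: np.ndarray, diag_b: np.ndarray, t: float) -> bool:
    """Is there a perfect matching using only assignments of cost <= t?

    Left side: bars of A plus one diagonal slot per bar of B; right side:
    bars of B plus one diagonal slot per bar of A.  Diagonal-to-diagonal is
    always allowed.
    """
    n, m = cost.shape
    rows, cols = [], []
    ii, jj = np.nonzero(cost <= t)
    rows.extend(ii)
    cols.extend(jj)
    for i in np.flatnonzero(diag_a <= t):
        rows.append(i)
        cols.append(m + i)
    for j in np.flatnonzero(diag_b <= t):
        rows.append(n + j)
        cols.append(j)
    for j in range(m):
        for i in range(n):
            rows.append(n + j)
            cols.append(m + i)
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n + m, n + m)
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return bool(np.all(match >= 0))


def bottleneck_distance(a: Barcode, b: Barcode, relative_error: float = 1e-4) -> float:
    """Bottleneck distance between two barcodes of the same degree/units."""
    _check_comparable(a, b)
    if not relative_error > 0:
        raise ValueError("relative_error must be > 0")
    A, B = _finite_bars(a), _finite_bars(b)
    n, m = len(A), len(B)
    if n == 0 and m == 0:
        return 0.0
    diag_a = (A[:, 1] - A[:, 0]) / 2.0 if n else np.zeros(0)
    diag_b = (B[:, 1] - B[:, 0]) / 2.0 if m else np.zeros(0)
    if n == 0:
        return float(diag_b.max())
    if m == 0:
        return float(diag_a.max())
    cost = np.max(np.abs(A[:, None, :] - B[None, :, :]), axis=2)
    candidates = np.unique(np.concatenate([cost.ravel(), diag_a, diag_b, [0.0]]))
    lo, hi = 0, len(candidates) - 1
    if _matching_feasible(cost, diag_a, diag_b, candidates[lo]):
        return float(candidates[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _matching_feasible(cost, diag_a, diag_b, candidates[mid]):
            hi = mid
        else:
            lo = mid
    return float(candidates[hi])


def wasserstein_distance(a: Barcode, b: Barcode, order: float = 2.0) -> float:
    """Wasserstein distance of the given order (>= 1) between two barcodes."""
    _check_comparable(a, b)
    if order < 1:
        raise ValueError("order must be >= 1")
    A, B = _finite_bars(a), _finite_bars(b)
    n, m = len(A), len(B)
    if n == 0 and m == 0:
        return 0.0
    q = float(order)
    full = np.zeros((n + m, n + m))
    if n and m:
        full[:n, :m] = np.max(np.abs(A[:, None, :] - B[None, :, :]), axis=2) ** q
    if n:
        full[:n, m:] = np.tile(((A[:, 1] - A[:, 0]) / 2.0) ** q, (n, 1)).T
    if m:
        full[n:, :m] = np.tile(((B[:, 1] - B[:, 0]) / 2.0) ** q, (m, 1))
    rows, cols = linear_sum_assignment(full)
    return float(full[rows, cols].sum() ** (1.0 / q))


def total_persistence(b: Barcode) -> float:
    """Sum of (death - birth) over all bars; essential bars must be capped."""
    return b.total_persistence()
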
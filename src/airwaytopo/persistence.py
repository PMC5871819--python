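"""Persistence barcodes over Z2.

Two filtration styles are supported:

* sublevel filtrations of a scalar function on an embedded graph (degree 0,
  computed by a union-find sweep with the elder rule) — used for the
  directional-complexity descriptors, where the function is depth below the
  top of the scan and the nested spaces are the parts of the tree above a
  horizontal plane sliding downwards;
* arbitrary filtered simplicial complexes up to dimension 3 (degrees 0-2,
  computed by boundary-matrix reduction with the twist/clearing optimisation)
  — used for alpha complexes of point clouds.

All homology is with coefficients in the field of two elements.  Bars with
``birth == death`` carry no topological information and are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import TreeParseError, UnitMismatchError
from .tree import AirwayTree

__all__ = [
    "Barcode",
    "FiltrationFunction",
    "FilteredComplex",
    "sublevel_barcode_deg0",
    "persistence",
    "read_diagram",
    "write_diagram",
]


@dataclass(frozen=True)
class Barcode:
    """A degree-n multiset of (birth, death) intervals.

    ``death`` may be ``math.inf`` for essential classes.  ``units`` names the
    scale of the filtration parameter (``"mm_depth"`` for height filtrations,
    ``"mm_radius"`` for alpha filtrations).  ``fmax`` records the maximum
    filtration value of the generating construction (depth of the bounding
    box, largest alpha radius); it is the documented cap applied to essential
    bars before distance computations.
    """

    degree: int
    bars: tuple[tuple[float, float], ...]
    units: str = "mm"
    fmax: float | None = None

    def __post_init__(self) -> None:
        for b, d in self.bars:
            if not b <= d:
                raise ValueError(f"bar with birth {b} > death {d}")
        object.__setattr__(
            self, "bars", tuple(sorted((float(b), float(d)) for b, d in self.bars))
        )

    def __len__(self) -> int:
        return len(self.bars)

    def finite(self) -> "Barcode":
        return replace(self, bars=tuple(bd for bd in self.bars if math.isfinite(bd[1])))

    def n_infinite(self) -> int:
        return sum(1 for _, d in self.bars if math.isinf(d))

    def capped(self, at: float | None = None) -> "Barcode":
        """Replace infinite deaths by ``at`` (default: the construction's
        maximum filtration value ``fmax``).  Bars that become zero-length
        are dropped."""
        if at is None:
            at = self.fmax
        if at is None:
            if self.n_infinite():
                raise ValueError("no cap value available for essential bars")
            return self
        bars = []
        for b, d in self.bars:
            d = min(d, float(at))
            if b < d:
                bars.append((b, d))
        return replace(self, bars=tuple(bars))

    def total_persistence(self) -> float:
        """Sum of bar lengths; requires all bars finite (cap first)."""
        if self.n_infinite():
            raise ValueError("total persistence undefined with essential bars; cap first")
        return float(sum(d - b for b, d in self.bars))


@dataclass(frozen=True)
class FiltrationFunction:
    """Scalar function on the vertices of a graph.

    Edges take the maximum of their endpoint values, so the sublevel set at
    level h is the full subgraph induced by the vertices with value <= h.
    """

    vertex_values: dict[int, float]

    def __getitem__(self, node_id: int) -> float:
        return self.vertex_values[int(node_id)]


def sublevel_barcode_deg0(tree: AirwayTree, f: FiltrationFunction) -> Barcode:
    """Degree-0 barcode of the sublevel filtration of ``f`` on ``tree``.

    A bar (h1, h2) records a connected component that first appears in the
    sublevel set at level h1 and merges, at level h2, into a component that
    was born earlier (the elder rule).  Each connected component of the graph
    contributes one essential bar born at the component's minimum value.

    Tie-breaking is deterministic: vertices are processed in (value, node_id)
    order and an edge after any vertex of equal value.
    """
    values = {}
    for nid in tree.ids:
        nid = int(nid)
        if nid not in f.vertex_values:
            raise ValueError(f"filtration value missing for vertex {nid}")
        values[nid] = float(f.vertex_values[nid])

    order = sorted(range(tree.n_nodes), key=lambda k: (values[int(tree.ids[k])], int(tree.ids[k])))
    rank = {k: r for r, k in enumerate(order)}

    edges = tree.edges()
    edge_events = sorted(
        ((max(values[int(tree.ids[a])], values[int(tree.ids[b])]), a, b) for a, b in edges),
        key=lambda t: t[0],
    )

    # union-find; each root stores (birth_value, birth_rank)
    parent = list(range(tree.n_nodes))
    birth: dict[int, tuple[float, int]] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    bars: list[tuple[float, float]] = []
    vi, ei = 0, 0
    nv, ne = len(order), len(edge_events)
    while vi < nv or ei < ne:
        # vertices first at equal value
        if ei >= ne or (vi < nv and values[int(tree.ids[order[vi]])] <= edge_events[ei][0]):
            k = order[vi]
            birth[k] = (values[int(tree.ids[k])], rank[k])
            vi += 1
            continue
        w, a, b = edge_events[ei]
        ei += 1
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        # elder rule: the younger component dies
        if birth[ra] <= birth[rb]:
            elder, younger = ra, rb
        else:
            elder, younger = rb, ra
        b_val = birth[younger][0]
        if b_val < w:
            bars.append((b_val, w))
        parent[younger] = elder

    roots = {find(k) for k in range(tree.n_nodes)}
    for r in roots:
        bars.append((birth[r][0], math.inf))

    fmax = max(values.values()) if values else 0.0
    return Barcode(degree=0, bars=tuple(bars), units="mm_depth", fmax=fmax)


# ---------------------------------------------------------------------------
# Filtered complexes and matrix reduction


@dataclass
class FilteredComplex:
    """A filtered simplicial complex on integer vertex labels.

    ``simplices`` maps each simplex (a sorted tuple of vertex indices) to its
    real filtration value.  The complex must be closed under faces and the
    filtration monotone (face value <= coface value).
    """

    simplices: dict[tuple[int, ...], float]
    units: str = "mm_radius"
    provenance: list[str] = field(default_factory=list)

    def max_dim(self) -> int:
        return max((len(s) - 1 for s in self.simplices), default=-1)

    def fmax(self) -> float:
        return max(self.simplices.values(), default=0.0)

    def validate(self) -> None:
        for s, v in self.simplices.items():
            if len(s) > 1:
                for f in _facets(s):
                    if f not in self.simplices:
                        raise ValueError(f"complex not closed under faces: {f}")
                    if self.simplices[f] > v + 1e-12:
                        raise ValueError(f"filtration not monotone at {s}")


def _facets(s: tuple[int, ...]):
    for i in range(len(s)):
        yield s[:i] + s[i + 1 :]


def _reduce_complex(cx: FilteredComplex) -> dict[int, list[tuple[float, float]]]:
    """Z2 persistence pairing by column reduction, processed one dimension at
    a time from the top down with clearing of paired creator columns."""
    order = sorted(cx.simplices, key=lambda s: (cx.simplices[s], len(s), s))
    index = {s: i for i, s in enumerate(order)}
    values = [cx.simplices[s] for s in order]
    maxdim = cx.max_dim()
    by_dim: list[list[int]] = [[] for _ in range(maxdim + 1)]
    for i, s in enumerate(order):
        by_dim[len(s) - 1].append(i)

    cleared: set[int] = set()
    destroyer: set[int] = set()
    pairs: list[tuple[int, int]] = []
    essentials: list[int] = []

    for d in range(maxdim, 0, -1):
        pivot_owner: dict[int, set[int]] = {}
        for j in by_dim[d]:
            if j in cleared:
                continue
            col = {index[f] for f in _facets(order[j])}
            while col:
                p = max(col)
                if p in pivot_owner:
                    col ^= pivot_owner[p]
                else:
                    break
            if col:
                p = max(col)
                pivot_owner[p] = col
                pairs.append((p, j))
                destroyer.add(j)
                cleared.add(p)
        # creators of dimension d that were never destroyed
        if d == maxdim:
            for j in by_dim[d]:
                if j not in destroyer:
                    essentials.append(j)
    for j in by_dim[0]:
        if j not in cleared:
            essentials.append(j)
    # dims 1..maxdim-1: creators are the cleared-complement minus destroyers
    for d in range(1, maxdim):
        for j in by_dim[d]:
            if j not in cleared and j not in destroyer:
                essentials.append(j)

    diagrams: dict[int, list[tuple[float, float]]] = {k: [] for k in range(maxdim + 1)}
    for p, j in pairs:
        b, dth = values[p], values[j]
        if b < dth:
            diagrams[len(order[p]) - 1].append((b, dth))
    for j in essentials:
        diagrams[len(order[j]) - 1].append((values[j], math.inf))
    return diagrams


def persistence(cx: FilteredComplex, degree: int) -> Barcode:
    """Barcode of ``cx`` in the given homology degree (0, 1 or 2).

    The full reduction is performed once per complex and cached.
    """
    if degree not in (0, 1, 2):
        raise ValueError(f"unsupported degree {degree}; only 0, 1, 2")
    cached = getattr(cx, "_diagrams", None)
    if cached is None:
        cached = _reduce_complex(cx)
        cx._diagrams = cached  # type: ignore[attr-defined]
    bars = tuple(cached.get(degree, []))
    return Barcode(degree=degree, bars=bars, units=cx.units, fmax=cx.fmax())


# ---------------------------------------------------------------------------
# Plain-text diagram files


def write_diagram(barcode: Barcode, path: str | Path) -> None:
    """One ``birth death`` pair per line; ``inf`` marks essential bars."""
    lines = [f"# degree: {barcode.degree}", f"# units: {barcode.units}"]
    if barcode.fmax is not None:
        lines.append(f"# fmax: {float(barcode.fmax)!r}")
    for b, d in barcode.bars:
        lines.append(f"{b!r} {'inf' if math.isinf(d) else repr(d)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_diagram(path: str | Path) -> Barcode:
    path = Path(path)
    degree, units, fmax = None, "mm", None
    bars = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("degree:"):
                degree = int(body.split(":", 1)[1])
            elif body.startswith("units:"):
                units = body.split(":", 1)[1].strip()
            elif body.startswith("fmax:"):
                fmax = float(body.split(":", 1)[1])
            continue
        cols = line.split()
        if len(cols) != 2:
            raise TreeParseError(f"{path}:{lineno}: expected 'birth death'")
        try:
            b = float(cols[0])
            d = math.inf if cols[1] == "inf" else float(cols[1])
        except ValueError as exc:
            raise TreeParseError(f"{path}:{lineno}: {exc}") from exc
        bars.append((b, d))
    if degree is None:
        raise TreeParseError(f"{path}: missing '# degree:' header")
    return Barcode(degree=degree, bars=tuple(bars), units=units, fmax=fmax)


def _check_comparable(a: Barcode, b: Barcode) -> None:
    if a.degree != b.degree or a.units != b.units:
        raise UnitMismatchError(
            f"cannot compare degree-{a.degree} [{a.units}] with "
            f"degree-{b.degree} [{b.units}]"
        )
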
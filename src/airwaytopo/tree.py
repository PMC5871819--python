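"""Embedded airway centerline trees.

An airway tree is the centerline graph of a segmented bronchial tree: a rooted
forest of nodes embedded in scanner coordinates (millimetres), densely sampled
so that the polyline between two branch points follows the true shape of the
airway (clinical extractions place up to a few hundred nodes between
consecutive bifurcations).  Two plain-text dialects are supported:

* SWC — the standard embedded-morphology format (7 whitespace-separated
  columns: id, type, x, y, z, radius, parent; ``#`` comments).  Airway trees do
  not use the neuronal structure types, so the type column carries the airway
  generation label when one is known, and ``0`` otherwise.
* ``branch_csv`` — a header row ``node_id,x,y,z,parent_id[,generation]``.

Coordinate convention: right-handed axes with the third coordinate pointing
superior (toward the head), so "top of the scan" means the largest z.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import MissingLabelsError, TreeParseError, TreeStructureError

__all__ = [
    "AirwayTree",
    "ScanMeta",
    "read_tree",
    "write_tree",
    "rotate_tree",
    "tree_length",
    "branch_point_count",
    "prune_to_generation",
]

GROUPS = ("HNS", "HS", "Mild", "Mod")
PHASES = ("inspiratory", "expiratory")


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan cohort metadata.

    ``group`` is the smoking/spirometry stratum (healthy non-smoker, healthy
    smoker, mild COPD = GOLD 1, moderate COPD = GOLD 2); ``phase`` is the
    breath-hold phase of the CT acquisition.  ``body_height`` (metres) is used
    only for height-normalised descriptor variants.
    """

    participant_id: str
    group: str
    phase: str
    body_height: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.body_height is not None and not self.body_height > 0:
            raise ValueError("body_height must be > 0 when present")


@dataclass
class AirwayTree:
    """A rooted forest of centerline nodes embedded in mm coordinates.

    Attributes
    ----------
    ids : (n,) int array of unique node identifiers.
    positions : (n, 3) float array, mm.
    parent_ids : (n,) int array; ``-1`` marks a root.  Multi-root files are
        accepted as forests (left/right lungs may arrive as separate
        components).
    generations : (n,) int array of airway generation labels, or None.
    radii : (n,) float array (read from SWC, unused by descriptors), or None.
    provenance : list of strings logging source file and transforms.
    """

    ids: np.ndarray
    positions: np.ndarray
    parent_ids: np.ndarray
    generations: np.ndarray | None = None
    radii: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        if self.generations is not None:
            self.generations = np.asarray(self.generations, dtype=np.int64)
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
        self.validate()

    # -- structural queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[int, int]:
        """Map node id -> row index."""
        return {int(i): k for k, i in enumerate(self.ids)}

    def edges(self) -> np.ndarray:
        """(m, 2) array of (child_index, parent_index) row pairs."""
        idx = self.index_of()
        out = [
            (k, idx[int(p)])
            for k, p in enumerate(self.parent_ids)
            if p != -1
        ]
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    def children_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        idx = self.index_of()
        for p in self.parent_ids:
            if p != -1:
                counts[idx[int(p)]] += 1
        return counts

    def root_indices(self) -> np.ndarray:
        return np.flatnonzero(self.parent_ids == -1)

    def component_labels(self) -> np.ndarray:
        """Connected-component label per node (one per root)."""
        idx = self.index_of()
        labels = np.full(self.n_nodes, -1, dtype=np.int64)
        for k in range(self.n_nodes):
            chain = []
            j = k
            while labels[j] == -1:
                chain.append(j)
                p = self.parent_ids[j]
                if p == -1:
                    labels[j] = j
                    break
                j = idx[int(p)]
            root = labels[j]
            for c in chain:
                labels[c] = root
        # relabel 0..k-1
        _, compact = np.unique(labels, return_inverse=True)
        return compact

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        ids = self.ids
        if len(np.unique(ids)) != len(ids):
            dup = ids[np.argmax(np.unique(ids, return_counts=True)[1] > 1)]
            raise TreeStructureError(f"duplicate node_id {int(dup)}")
        if not np.all(np.isfinite(self.positions)):
            raise TreeStructureError("non-finite node position")
        idx = self.index_of()
        for k, p in enumerate(self.parent_ids):
            p = int(p)
            if p == -1:
                continue
            if p not in idx:
                raise TreeStructureError(
                    f"node {int(ids[k])} references missing parent {p}"
                )
        # cycle check by traversal toward roots
        state = np.zeros(self.n_nodes, dtype=np.int8)  # 0 new, 1 active, 2 done
        for k in range(self.n_nodes):
            j, path = k, []
            while state[j] == 0:
                state[j] = 1
                path.append(j)
                p = int(self.parent_ids[j])
                if p == -1:
                    break
                j = idx[p]
                if state[j] == 1:
                    raise TreeStructureError(
                        f"cycle through node {int(ids[j])}"
                    )
            for c in path:
                state[c] = 2
        if self.generations is not None:
            if np.any(self.generations < 0):
                raise TreeStructureError("negative generation label")
            for k, p in enumerate(self.parent_ids):
                if p == -1:
                    continue
                gp = int(self.generations[idx[int(p)]])
                gc = int(self.generations[k])
                if gc not in (gp, gp + 1):
                    raise TreeStructureError(
                        f"generation of node {int(ids[k])} ({gc}) is not "
                        f"parent's ({gp}) or parent's + 1"
                    )


# ---------------------------------------------------------------------------
# I/O


def _parse_swc(text: str, source: str) -> AirwayTree:
    ids, xyz, radii, parents, types = [], [], [], [], []
    seen: set[int] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.replace("−", "-").split()
        if len(cols) != 7:
            raise TreeParseError(
                f"{source}:{lineno}: expected 7 columns, got {len(cols)}"
            )
        try:
            nid = int(cols[0])
            typ = int(cols[1])
            x, y, z, r = (float(c) for c in cols[2:6])
            par = int(cols[6])
        except ValueError as exc:
            raise TreeParseError(f"{source}:{lineno}: {exc}") from exc
        if nid in seen:
            raise TreeParseError(f"{source}:{lineno}: duplicate node_id {nid}")
        seen.add(nid)
        ids.append(nid)
        types.append(typ)
        xyz.append((x, y, z))
        radii.append(r)
        parents.append(par)
    if not ids:
        raise TreeParseError(f"{source}: no node records")
    gen = np.asarray(types, dtype=np.int64)
    generations = gen if np.any(gen != 0) else None
    return AirwayTree(
        ids=np.asarray(ids),
        positions=np.asarray(xyz),
        parent_ids=np.asarray(parents),
        generations=generations,
        radii=np.asarray(radii),
        provenance=[f"read swc {source}"],
    )


def _parse_branch_csv(text: str, source: str) -> AirwayTree:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TreeParseError(f"{source}: empty file")
    header = [h.strip() for h in lines[0].split(",")]
    required = ["node_id", "x", "y", "z", "parent_id"]
    if header[: len(required)] != required:
        raise TreeParseError(
            f"{source}:1: header must start with {','.join(required)}"
        )
    has_gen = len(header) > 5 and header[5] == "generation"
    ids, xyz, parents, gens = [], [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = [c.strip() for c in line.split(",")]
        try:
            ids.append(int(cols[0]))
            xyz.append(tuple(float(c) for c in cols[1:4]))
            parents.append(int(cols[4]))
            if has_gen:
                gens.append(int(cols[5]))
        except (ValueError, IndexError) as exc:
            raise TreeParseError(f"{source}:{lineno}: {exc}") from exc
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise TreeParseError(f"{source}: duplicate node_id {dup}")
    return AirwayTree(
        ids=np.asarray(ids),
        positions=np.asarray(xyz),
        parent_ids=np.asarray(parents),
        generations=np.asarray(gens) if has_gen else None,
        provenance=[f"read branch_csv {source}"],
    )


def read_tree(path: str | Path, dialect: str = "swc") -> AirwayTree:
    """Read an airway centerline tree from ``path``.

    Parameters
    ----------
    dialect : {"swc", "branch_csv"}
        File dialect; see module docstring.  Coordinates are taken verbatim
        as millimetres.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "swc":
        return _parse_swc(text, str(path))
    if dialect == "branch_csv":
        return _parse_branch_csv(text, str(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tree(tree: AirwayTree, path: str | Path) -> None:
    """Write ``tree`` as SWC, parseable by :func:`read_tree`.

    Generation labels (when present) are stored in the SWC type column;
    provenance lines are written as ``#`` comments.
    """
    if tree.n_nodes == 0:
        raise ValueError("refusing to write a tree with no nodes")
    buf = io.StringIO()
    for line in tree.provenance:
        buf.write(f"# {line}\n")
    gen = tree.generations
    radii = tree.radii
    for k in range(tree.n_nodes):
        typ = int(gen[k]) if gen is not None else 0
        r = float(radii[k]) if radii is not None else 1.0
        x, y, z = (float(v) for v in tree.positions[k])
        buf.write(
            f"{int(tree.ids[k])} {typ} {x!r} {y!r} {z!r} {r!r} "
            f"{int(tree.parent_ids[k])}\n"
        )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Geometry and descriptors


def rotation_matrix(angles_deg) -> np.ndarray:
    """Rotation about the fixed lab axes in the order X, then Y, then Z
    (right-hand rule), i.e. ``R = Rz(c) @ Ry(b) @ Rx(a)``."""
    a, b, c = (math.radians(float(v)) for v in angles_deg)
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rotate_tree(tree: AirwayTree, angles_deg) -> AirwayTree:
    """Rotate node positions rigidly; topology and labels are unchanged."""
    angles = np.asarray(angles_deg, dtype=float)
    if angles.shape != (3,) or not np.all(np.isfinite(angles)):
        raise ValueError("angles_deg must be 3 finite values")
    rot = rotation_matrix(angles)
    out = replace(
        tree,
        positions=tree.positions @ rot.T,
        provenance=tree.provenance
        + [f"rotate_deg x={angles[0]} y={angles[1]} z={angles[2]}"],
    )
    return out


def tree_length(tree: AirwayTree) -> int:
    """Number of centerline vertices.

    At a fixed, uniform arc-length sampling density the vertex count is
    proportional to the physical length of the bronchial tree, so the count
    serves as a length proxy.  Includes the dense inter-branch-point vertices,
    not only the bifurcations.
    """
    return tree.n_nodes


def branch_point_count(tree: AirwayTree) -> int:
    """Number of nodes where airways branch out (out-degree >= 2).

    A trifurcation counts once.
    """
    return int(np.sum(tree.children_counts() >= 2))


def prune_to_generation(tree: AirwayTree, min_generation: int) -> AirwayTree:
    """Keep only nodes with generation >= ``min_generation``.

    Nodes whose parent is removed become roots, so the result is a forest of
    the distal subtrees.  Requires generation labels.
    """
    if tree.generations is None:
        raise MissingLabelsError("prune_to_generation requires generation labels")
    keep = tree.generations >= int(min_generation)
    kept_ids = set(int(i) for i in tree.ids[keep])
    parents = tree.parent_ids[keep].copy()
    for k, p in enumerate(parents):
        if int(p) not in kept_ids:
            parents[k] = -1
    return AirwayTree(
        ids=tree.ids[keep],
        positions=tree.positions[keep],
        parent_ids=parents,
        generations=tree.generations[keep],
        radii=tree.radii[keep] if tree.radii is not None else None,
        provenance=tree.provenance + [f"prune min_generation={int(min_generation)}"],
    )
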
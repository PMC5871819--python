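"""Seeded synthetic airway trees, voxel phantoms and multi-group cohorts.

Patient CT data of the kind these descriptors were designed for are not
publicly distributable, so every pipeline stage is exercised on synthetic
stand-ins that reproduce the *structural* properties the descriptors assume:

* trees are rooted dichotomously-branching polylines grown downward from a
  trachea-like trunk, densely sampled at a uniform arc-length step (the
  vertex-count length proxy is only meaningful at fixed sampling density, so
  uniform spacing is enforced and stamped into provenance);
* upward trajectory changes — the events upwards complexity counts — are
  inserted as Poisson events along branches: a short sub-segment of the
  branch is bent to ascend before the branch resumes its descent, creating
  one local top per event;
* phantoms are hollow ellipsoid "lobes" with embedded tube "airways" on a
  voxel grid (default 0.7 mm isotropic), with a synthetic HU volume whose
  below-threshold fraction is known exactly;
* cohorts follow the four-group smoking/severity design (HNS, HS, Mild,
  Mod).  Severity presets shrink the visible tree (fewer generations —
  disease obstructs the peripheral airways visible in CT) while *raising*
  the per-branch upward-turn rate (disease distorts the surviving branches);
  the net upward-turn count still falls with severity because branch count
  falls faster, which keeps upwards complexity and tree length positively
  correlated, as observed in real cohorts.
* expiratory trees are derived from inspiratory ones by a deflation
  transform: cranio-caudal (axial) compression plus radial crowding toward
  the trunk axis and a mild buckling of branch trajectories.  Crowding moves
  branches closer together, so loops between neighbouring branches form at
  smaller thickening radii and new contacts appear, raising branch-to-branch
  proximity; buckling adds small upward excursions, changing the shape (not
  just the scale) of the depth barcode between phases.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .tree import GROUPS, AirwayTree, write_tree
from .volumes import VoxelVolume, write_volume

__all__ = [
    "TreeGenParams",
    "PhantomParams",
    "TreeEventLog",
    "generate_airway_tree",
    "generate_lung_phantom",
    "hollow_sphere_volume",
    "expiratory_transform",
    "default_group_presets",
    "generate_cohort",
]


@dataclass(frozen=True)
class TreeGenParams:
    """Parameters of the recursive airway-tree generator.

    ``generations`` counts branching levels (the trunk is generation 0).
    ``branch_length_mm`` is the (mean, sd) of the trunk length; deeper
    branches shrink by ``length_decay`` per generation, mimicking the
    roughly geometric length scaling of real airways.
    ``upward_turn_rate`` is the expected number of upward deflections
    inserted per branch (Poisson).  ``node_spacing_mm`` is the uniform
    arc-length step of the centerline sampling.
    """

    generations: int = 10
    branch_length_mm: tuple[float, float] = (45.0, 5.0)
    length_decay: float = 0.8
    branching_angle_deg: tuple[float, float] = (35.0, 8.0)
    upward_turn_rate: float = 0.3
    turn_length_mm: tuple[float, float] = (2.5, 0.5)
    node_spacing_mm: float = 0.35
    trunk_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not self.node_spacing_mm > 0:
            raise ValueError("node_spacing_mm must be > 0")
        if self.upward_turn_rate < 0:
            raise ValueError("upward_turn_rate must be >= 0")
        if not 0 < self.length_decay <= 1:
            raise ValueError("length_decay must be in (0, 1]")


@dataclass
class TreeEventLog:
    """Ground-truth bookkeeping emitted alongside a generated tree."""

    n_nodes: int = 0
    n_branches: int = 0
    n_bifurcations: int = 0
    n_upward_turns: int = 0
    nodes_per_generation: dict[int, int] = field(default_factory=dict)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, a))
    return u, np.cross(d, u)


def generate_airway_tree(params: TreeGenParams) -> tuple[AirwayTree, TreeEventLog]:
    """Grow a synthetic bronchial tree; same params + seed give identical
    output, byte-for-byte through SWC round trips."""
    rng = np.random.default_rng(int(params.seed))
    spacing = params.node_spacing_mm
    log = TreeEventLog()

    ids: list[int] = []
    pos: list[np.ndarray] = []
    par: list[int] = []
    gen: list[int] = []
    next_id = 1

    # stack of branches to grow: (start position, direction, parent node id, generation)
    root_dir = _unit(np.asarray(params.trunk_direction, dtype=float))
    stack = [(np.zeros(3), root_dir, -1, 0)]
    while stack:
        start, d, parent_id, g = stack.pop()
        log.n_branches += 1
        mean_len = params.branch_length_mm[0] * params.length_decay**g
        sd_len = params.branch_length_mm[1] * params.length_decay**g
        length = max(float(rng.normal(mean_len, sd_len)), 4 * spacing)
        n_steps = max(int(round(length / spacing)), 3)

        # upward deflection events: non-overlapping ascending runs
        step_dirs = [d] * n_steps
        up = d.copy()
        up[2] = abs(up[2])
        if np.linalg.norm(up) == 0 or up[2] == 0:
            up = np.array([0.0, 0.0, 1.0])
        up = _unit(up)
        n_events = int(rng.poisson(params.upward_turn_rate))
        turn_steps = max(int(round(rng.normal(*params.turn_length_mm) / spacing)), 2)
        placed = 0
        if n_events > 0:
            slot = turn_steps + 2
            avail = max(n_steps - 2, 0) // slot
            k = min(n_events, avail)
            if k > 0:
                starts = rng.choice(avail, size=k, replace=False)
                for s in np.sort(starts):
                    i0 = 1 + int(s) * slot
                    for t in range(turn_steps):
                        step_dirs[i0 + t] = up
                    placed += 1
        log.n_upward_turns += placed

        # lay down nodes at exact uniform arc-length spacing
        p = start.copy()
        if parent_id == -1:
            ids.append(next_id)
            pos.append(p.copy())
            par.append(-1)
            gen.append(g)
            last = next_id
            next_id += 1
        else:
            last = parent_id
        for sd in step_dirs:
            p = p + sd * spacing
            ids.append(next_id)
            pos.append(p.copy())
            par.append(last)
            gen.append(g)
            last = next_id
            next_id += 1

        if g + 1 < params.generations:
            log.n_bifurcations += 1
            u, v = _perp_frame(d)
            phi = rng.uniform(0, 2 * math.pi)
            for s in (0, 1):
                theta = math.radians(
                    max(float(rng.normal(*params.branching_angle_deg)), 5.0) / 2.0
                )
                az = phi + s * math.pi + rng.normal(0, 0.3)
                child = (
                    math.cos(theta) * d
                    + math.sin(theta) * (math.cos(az) * u + math.sin(az) * v)
                )
                if child[2] > -0.05:
                    child[2] = -abs(child[2]) - 0.1
                child = _unit(child)
                stack.append((p.copy(), child, last, g + 1))

    tree = AirwayTree(
        ids=np.asarray(ids),
        positions=np.asarray(pos),
        parent_ids=np.asarray(par),
        generations=np.asarray(gen),
        provenance=[
            f"synthetic seed={params.seed} generations={params.generations} "
            f"upward_turn_rate={params.upward_turn_rate} "
            f"node_spacing_mm={spacing}"
        ],
    )
    log.n_nodes = tree.n_nodes
    vals, counts = np.unique(tree.generations, return_counts=True)
    log.nodes_per_generation = {int(a): int(b) for a, b in zip(vals, counts)}
    return tree, log


# ---------------------------------------------------------------------------
# Phase transform


def expiratory_transform(
    tree: AirwayTree,
    axial_compression: float = 0.85,
    radial_crowding: float = 0.75,
    buckling_amplitude_mm: float = 6.0,
    buckling_wavelength_mm: float = 25.0,
) -> AirwayTree:
    """Derive an expiratory tree from an inspiratory one.

    Deflation is modelled as compression toward the top of the trunk:
    ``axial_compression`` scales the vertical (z) extent, ``radial_crowding``
    scales the horizontal distance of every node from the trunk axis, and a
    deterministic sinusoidal buckling of amplitude ``buckling_amplitude_mm``
    and wavelength ``buckling_wavelength_mm`` (applied along the node order,
    vertically) emulates airway distortion under deflation.  With
    ``axial_compression = radial_crowding = 1`` and zero amplitude this is
    the identity.
    """
    root = tree.positions[tree.root_indices()[0]] if tree.n_nodes else np.zeros(3)
    q = tree.positions - root
    out = q.copy()
    out[:, :2] *= radial_crowding
    out[:, 2] *= axial_compression
    if buckling_amplitude_mm > 0:
        # arc position proxy: cumulative index along the stored node order,
        # which follows branches contiguously
        s = np.arange(tree.n_nodes) * _median_step(tree)
        out[:, 2] += buckling_amplitude_mm * np.sin(
            2 * math.pi * s / buckling_wavelength_mm
        )
    return replace(
        tree,
        positions=out + root,
        provenance=tree.provenance
        + [
            f"expiratory axial={axial_compression} radial={radial_crowding} "
            f"buckle={buckling_amplitude_mm}mm/{buckling_wavelength_mm}mm"
        ],
    )


def _median_step(tree: AirwayTree) -> float:
    e = tree.edges()
    if len(e) == 0:
        return 1.0
    d = np.linalg.norm(tree.positions[e[:, 0]] - tree.positions[e[:, 1]], axis=1)
    return float(np.median(d))


# ---------------------------------------------------------------------------
# Voxel phantoms


@dataclass(frozen=True)
class PhantomParams:
    """Hollow-lobe phantom: an ellipsoidal shell with embedded airway tubes.

    The HU volume fills the lobe interior with parenchyma-like attenuation
    (normal around ``hu_mean``) and implants an exact fraction of
    emphysema-like voxels below -950 HU.
    """

    lobe_semi_axes_mm: tuple[float, float, float] = (24.0, 20.0, 28.0)
    airway_radius_mm: float = 2.5
    voxel_spacing_mm: float = 0.7
    emphysema_fraction: float = 0.10
    hu_mean: float = -850.0
    hu_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(a > 0 for a in self.lobe_semi_axes_mm):
            raise ValueError("semi-axes must be > 0")
        if not self.voxel_spacing_mm > 0:
            raise ValueError("voxel spacing must be > 0")
        if not 0 <= self.emphysema_fraction <= 1:
            raise ValueError("emphysema_fraction in [0, 1]")
        if self.airway_radius_mm >= min(self.lobe_semi_axes_mm):
            raise ValueError("airway tube exceeds the lobe")


def _surface_of(mask: np.ndarray) -> np.ndarray:
    interior = ndimage.binary_erosion(mask)
    return mask & ~interior


def generate_lung_phantom(
    params: PhantomParams,
) -> tuple[dict[str, VoxelVolume], dict[str, float]]:
    """Build the phantom volumes and exact ground-truth counts.

    Returns (volumes, truth) where volumes has keys ``surface_labels``
    (lobe shell + airway luminal surface), ``lumen_mask``, ``lung_mask`` and
    ``hu``; truth records lumen/shell voxel counts and the exact fraction of
    lung voxels below -950 HU.
    """
    rng = np.random.default_rng(int(params.seed))
    h = params.voxel_spacing_mm
    a = np.asarray(params.lobe_semi_axes_mm)
    margin = 2 * h
    half = a + margin
    n = np.ceil(2 * half / h).astype(int) + 1
    origin = -half
    ax = [origin[i] + h * np.arange(n[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    interior = (X / a[0]) ** 2 + (Y / a[1]) ** 2 + (Z / a[2]) ** 2 <= 1.0
    shell = _surface_of(interior)

    # airway: vertical trunk tube from the top pole to centre, then two
    # angled child tubes
    r = params.airway_radius_mm
    segs = [
        (np.array([0.0, 0.0, a[2] * 0.95]), np.array([0.0, 0.0, 0.0])),
        (np.array([0.0, 0.0, 0.0]), np.array([a[0] * 0.5, 0.0, -a[2] * 0.5])),
        (np.array([0.0, 0.0, 0.0]), np.array([-a[0] * 0.5, 0.0, -a[2] * 0.5])),
    ]
    pts = np.stack([X, Y, Z], axis=-1)
    lumen = np.zeros_like(interior)
    for p0, p1 in segs:
        seg = p1 - p0
        L2 = float(seg @ seg)
        w = pts - p0
        t = np.clip(np.einsum("xyzc,c->xyz", w, seg) / L2, 0.0, 1.0)
        closest = p0 + t[..., None] * seg
        dist2 = np.sum((pts - closest) ** 2, axis=-1)
        lumen |= dist2 <= r * r
    lumen &= interior
    tube_surface = _surface_of(lumen)

    surface = (shell | tube_surface).astype(np.uint8)
    lung = (interior & ~lumen).astype(np.uint8)

    hu_grid = np.full(interior.shape, -1024.0)
    lung_idx = np.argwhere(lung == 1)
    hu_grid[lung == 1] = rng.normal(params.hu_mean, params.hu_sd, size=len(lung_idx))
    k = int(round(params.emphysema_fraction * len(lung_idx)))
    if k > 0:
        sel = rng.choice(len(lung_idx), size=k, replace=False)
        ii = lung_idx[sel]
        hu_grid[ii[:, 0], ii[:, 1], ii[:, 2]] = rng.uniform(-1000.0, -960.0, size=k)
    hu_grid = np.rint(hu_grid).astype(np.int16)

    spacing = (h, h, h)
    org = tuple(float(o) for o in origin)
    prov = [f"phantom seed={params.seed}"]
    vols = {
        "surface_labels": VoxelVolume(surface, spacing, org, "surface_labels", list(prov)),
        "lumen_mask": VoxelVolume(lumen.astype(np.uint8), spacing, org, "lumen_mask", list(prov)),
        "lung_mask": VoxelVolume(lung, spacing, org, "lung_mask", list(prov)),
        "hu": VoxelVolume(hu_grid, spacing, org, "hu_attenuation", list(prov)),
    }
    n_lung = int(lung.sum())
    truth = {
        "lumen_voxels": int(lumen.sum()),
        "shell_voxels": int(shell.sum()),
        "lung_voxels": n_lung,
        "emphysema_fraction_actual": float(
            np.sum(hu_grid[lung == 1] < -950) / max(n_lung, 1)
        ),
    }
    return vols, truth


def hollow_sphere_volume(
    radius_mm: float = 10.0, spacing_mm: float = 0.7
) -> VoxelVolume:
    """Binary shell of a sphere, for exercising the void descriptor: the
    dominant degree-2 bar of its surface voxels dies near ``radius_mm``."""
    half = radius_mm + 2 * spacing_mm
    n = int(np.ceil(2 * half / spacing_mm)) + 1
    ax = -half + spacing_mm * np.arange(n)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    # voxels whose centre is within half a spacing of the sphere: a shell
    # centred on the true surface, not biased inward like an eroded ball
    shell = (np.abs(r - radius_mm) <= spacing_mm / 2).astype(np.uint8)
    return VoxelVolume(
        shell,
        (spacing_mm,) * 3,
        (-half,) * 3,
        "surface_labels",
        [f"hollow sphere R={radius_mm}mm"],
    )


# ---------------------------------------------------------------------------
# Cohorts


def default_group_presets(
    node_spacing_mm: float = 0.35, scale: float = 1.0
) -> dict[str, TreeGenParams]:
    """Severity-graded tree parameters for the four study groups.

    ``scale`` < 1 shrinks all trees proportionally (fewer generations are
    not affected) for faster runs at reduced problem size.
    """
    L = 45.0 * scale
    base = dict(
        branch_length_mm=(L, 0.1 * L),
        node_spacing_mm=node_spacing_mm,
    )
    return {
        "HNS": TreeGenParams(generations=7, upward_turn_rate=0.30, **base),
        "HS": TreeGenParams(generations=6, upward_turn_rate=0.40, **base),
        "Mild": TreeGenParams(generations=5, upward_turn_rate=0.55, **base),
        "Mod": TreeGenParams(generations=4, upward_turn_rate=0.70, **base),
    }


def generate_cohort(
    out_dir: str | Path,
    n_per_group: dict[str, int] | None = None,
    presets: dict[str, TreeGenParams] | None = None,
    seed: int = 0,
    paired_phases: bool = True,
    axial_compression: float = 0.85,
    radial_crowding: float = 0.75,
    buckling_amplitude_mm: float = 6.0,
    with_phantoms: bool = False,
    phantom_spacing_mm: float = 1.5,
) -> pd.DataFrame:
    """Write a synthetic cohort (SWC trees, optional phantoms, manifest CSV).

    Returns the manifest table: one row per (participant, phase) with columns
    participant_id, group, phase, height_m, tree_path [, volume columns] and
    the generator's ground-truth event counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if n_per_group is None:
        n_per_group = {g: 4 for g in GROUPS}
    if presets is None:
        presets = default_group_presets()
    rng = np.random.default_rng(int(seed))

    rows = []
    pid_counter = 0
    for group in GROUPS:
        n = int(n_per_group.get(group, 0))
        for _ in range(n):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            tree_seed = int(rng.integers(0, 2**31 - 1))
            height = float(np.round(rng.normal(1.70, 0.09), 3))
            params = replace(presets[group], seed=tree_seed)
            tree, log = generate_airway_tree(params)
            phases = [("inspiratory", tree)]
            if paired_phases:
                phases.append(
                    (
                        "expiratory",
                        expiratory_transform(
                            tree,
                            axial_compression=axial_compression,
                            radial_crowding=radial_crowding,
                            buckling_amplitude_mm=buckling_amplitude_mm,
                        ),
                    )
                )
            row_common = dict(
                participant_id=pid,
                group=group,
                height_m=height,
                tree_seed=tree_seed,
                true_bifurcations=log.n_bifurcations,
                true_upward_turns=log.n_upward_turns,
                true_nodes=log.n_nodes,
            )
            for phase, t in phases:
                tree_path = out_dir / f"{pid}_{phase}.swc"
                write_tree(t, tree_path)
                rows.append(dict(row_common, phase=phase, tree_path=str(tree_path)))
            if with_phantoms:
                pp = PhantomParams(
                    voxel_spacing_mm=phantom_spacing_mm, seed=tree_seed
                )
                vols, truth = generate_lung_phantom(pp)
                for key in ("surface_labels", "lumen_mask", "lung_mask", "hu"):
                    vpath = out_dir / f"{pid}_{key}.nii.gz"
                    write_volume(vols[key], vpath)
                for r in rows[-len(phases):]:
                    r["surface_path"] = str(out_dir / f"{pid}_surface_labels.nii.gz")
                    r["lumen_path"] = str(out_dir / f"{pid}_lumen_mask.nii.gz")
                    r["lung_path"] = str(out_dir / f"{pid}_lung_mask.nii.gz")
                    r["hu_path"] = str(out_dir / f"{pid}_hu.nii.gz")
                    r["true_lumen_voxels"] = truth["lumen_voxels"]
                    r["true_emphysema_pct"] = 100 * truth["emphysema_fraction_actual"]

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
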
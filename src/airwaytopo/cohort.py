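"""Cohort aggregation: feature tables, distance matrices, embeddings and
group statistics.

The analysis mirrors a four-group COPD imaging study design: per-scan
descriptors are collected into a feature table, barcodes are compared
pairwise (bottleneck or Wasserstein-2), the resulting pseudo-metric space is
embedded in 2D by classical multidimensional scaling, and group differences
are assessed with pairwise two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import features as F
from .metrics import bottleneck_distance, wasserstein_distance
from .persistence import Barcode
from .tree import read_tree
from .volumes import emphysema_score, lumen_volume, read_volume

__all__ = [
    "DistanceMatrix",
    "pairwise_distances",
    "mds_embed",
    "ks_pairwise",
    "pearson",
    "build_feature_table",
    "linear_separability",
]

# Kolmogorov-Smirnov: exact null distribution up to this per-group size,
# asymptotic beyond it.
KS_EXACT_MAX_N = 25


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, metric: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(), metric)


def pairwise_distances(
    barcodes: list[Barcode],
    metric: str = "bottleneck",
    ids: list[str] | None = None,
    relative_error: float = 1e-4,
    order: float = 2.0,
    cap: float | str = "auto",
) -> DistanceMatrix:
    """All-pairs barcode distances.

    ``metric`` is ``"bottleneck"`` or ``"wasserstein2"``.  Essential bars are
    capped before comparison: with ``cap="auto"`` each barcode is capped at
    its own construction maximum (its ``fmax``); a float caps all barcodes at
    that value.
    """
    if len(barcodes) < 1:
        raise ValueError("need at least one barcode")
    deg = {b.degree for b in barcodes}
    units = {b.units for b in barcodes}
    if len(deg) > 1 or len(units) > 1:
        raise ValueError("barcodes must share degree and units")
    capped = [b.capped(None if cap == "auto" else float(cap)) for b in barcodes]
    n = len(capped)
    if ids is None:
        ids = [str(i) for i in range(n)]
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        if metric == "bottleneck":
            d = bottleneck_distance(capped[i], capped[j], relative_error)
        elif metric == "wasserstein2":
            d = wasserstein_distance(capped[i], capped[j], order)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(list(ids), mat, metric)


def mds_embed(dm: DistanceMatrix, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Double-centres the squared distances and takes the top eigenpairs.  The
    sign of each axis is fixed so that its largest-magnitude coordinate is
    positive, making the embedding fully deterministic.  Distances that are
    exactly Euclidean in ``n_dims`` dimensions are reproduced up to rigid
    motion.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("MDS embedding requires at least 3 scans")
    d2 = dm.matrix**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    idx = np.argsort(w)[::-1][:n_dims]
    lam = np.clip(w[idx], 0.0, None)
    coords = v[:, idx] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        a = int(np.argmax(np.abs(coords[:, k])))
        if coords[a, k] < 0:
            coords[:, k] = -coords[:, k]
    out = pd.DataFrame(coords, columns=[f"mds{i+1}" for i in range(n_dims)])
    out.insert(0, "scan_id", dm.ids)
    return out


def ks_pairwise(
    table: pd.DataFrame,
    feature: str,
    group_col: str = "group",
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sided two-sample KS tests of ``feature`` between groups.

    Returns one row per unordered group pair with the absolute KS statistic
    (sup |ECDF1 - ECDF2|) and the p-value (exact when min(n1, n2) <=
    ``KS_EXACT_MAX_N``, asymptotic otherwise).  Raw p-values are reported;
    ``holm=True`` adds a Holm-corrected column.
    """
    groups = {}
    for g, sub in table.groupby(group_col, sort=True):
        x = pd.to_numeric(sub[feature], errors="coerce").dropna().to_numpy()
        if len(x) < 2:
            warnings.warn(f"group {g!r} has < 2 observations; skipped")
            continue
        groups[g] = x
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    rows = []
    for g1, g2 in combinations(sorted(groups), 2):
        x, y = groups[g1], groups[g2]
        method = "exact" if min(len(x), len(y)) <= KS_EXACT_MAX_N else "asymp"
        res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
        rows.append(
            dict(group_1=g1, group_2=g2, ks=float(res.statistic),
                 p_value=float(res.pvalue), n_1=len(x), n_2=len(y))
        )
    out = pd.DataFrame(rows)
    if holm:
        p = out["p_value"].to_numpy()
        orderi = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(orderi):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(running, 1.0)
        out["p_holm"] = adj
    return out


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def linear_separability(coords: np.ndarray, labels) -> float:
    """Fraction of points correctly classified by the best linear rule on
    ``coords`` (fitted by logistic regression)."""
    from sklearn.linear_model import LogisticRegression

    labels = np.asarray(labels)
    clf = LogisticRegression(max_iter=1000)
    clf.fit(coords, labels)
    return float(np.mean(clf.predict(coords) == labels))


# ---------------------------------------------------------------------------
# Feature tables


def build_feature_table(
    manifest: pd.DataFrame | str | Path,
    angles_deg=None,
    emphysema_threshold_hu: int = -950,
    min_generation: int | None = None,
    proximity_max_points: int | None = 700,
    seed: int = 0,
) -> pd.DataFrame:
    """Compute all tree (and, when volume paths are present, volume)
    descriptors for every scan in a cohort manifest.

    The manifest needs columns participant_id, group, phase, height_m,
    tree_path; optional lumen_path/lung_path/hu_path columns enable the
    baseline features.  Per-row failures are recorded in an ``error`` column
    rather than aborting the run.
    """
    from .tree import branch_point_count, prune_to_generation, tree_length
    from .tree import ScanMeta

    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = ["participant_id", "group", "phase", "tree_path"]
    missing = [c for c in required if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")

    rows = []
    for _, mrow in manifest.iterrows():
        rec = {k: mrow[k] for k in manifest.columns if not str(k).endswith("_path")}
        rec["error"] = ""
        try:
            tree = read_tree(mrow["tree_path"], dialect="swc")
            if min_generation is not None:
                tree = prune_to_generation(tree, min_generation)
            rec["tree_length"] = tree_length(tree)
            rec["branch_points"] = branch_point_count(tree)
            comp = tree.component_labels()
            rec["n_components"] = int(comp.max()) + 1 if len(comp) else 0
            rec["upwards_complexity"] = F.upwards_complexity(tree)
            if angles_deg is not None:
                rec["directional_complexity"] = F.directional_complexity(
                    tree, angles_deg
                )
            rec["proximity_mm"] = F.branch_to_branch_proximity(
                tree, jitter_seed=seed, max_points=proximity_max_points
            )
            height = mrow.get("height_m", np.nan)
            if pd.notna(height) and float(height) > 0:
                meta = ScanMeta(
                    str(mrow["participant_id"]), str(mrow["group"]),
                    str(mrow["phase"]), float(height),
                )
                rec["upwards_complexity_per_m"] = F.normalize_by_height(
                    rec["upwards_complexity"], meta
                )
                rec["tree_length_per_m"] = F.normalize_by_height(
                    rec["tree_length"], meta
                )
            if "lumen_path" in manifest.columns and pd.notna(mrow.get("lumen_path")):
                rec["lumen_voxels"] = lumen_volume(
                    read_volume(mrow["lumen_path"], "lumen_mask")
                )
            if (
                "hu_path" in manifest.columns
                and pd.notna(mrow.get("hu_path"))
                and pd.notna(mrow.get("lung_path"))
            ):
                rec["emphysema_pct"] = emphysema_score(
                    read_volume(mrow["hu_path"], "hu_attenuation"),
                    read_volume(mrow["lung_path"], "lung_mask"),
                    emphysema_threshold_hu,
                )
        except Exception as exc:  # per-row failure policy
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows)
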
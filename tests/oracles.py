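"""Independent brute-force oracles used to validate the persistence core.

Everything here is deliberately naive: plain left-to-right boundary-matrix
reduction without optimisations, component tracking by recomputing connected
components at every filtration level, and exhaustive enumeration over
matchings.  None of it shares code with the package's implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def components_of(vertices: set[int], edges: list[tuple[int, int]]) -> list[set[int]]:
    """Connected components of the graph on ``vertices`` by flood fill."""
    adj: dict[int, set[int]] = {i: set() for i in vertices}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[int] = set()
    comps = []
    for i in sorted(vertices):
        if i in seen:
            continue
        comp, todo = set(), [i]
        while todo:
            v = todo.pop()
            if v in comp:
                continue
            comp.add(v)
            todo.extend(adj[v] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def sublevel_deg0_by_tracking(values: np.ndarray, edges: list[tuple[int, int]]):
    """Degree-0 sublevel barcode of a vertex-valued graph by recomputing the
    connected components of every sublevel set and tracking births/merges.

    A component is identified by its minimum-value vertex (ties by index).
    Returns a sorted list of (birth, death) with math.inf for essentials.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    levels = np.unique(values)
    alive: dict[int, float] = {}  # representative vertex -> birth value
    bars = []
    for h in levels:
        vset = {i for i in range(n) if values[i] <= h}
        sub_edges = [(a, b) for a, b in edges if a in vset and b in vset]
        comps = components_of(vset, sub_edges)
        rep = lambda c: min(c, key=lambda v: (values[v], v))
        new_alive: dict[int, float] = {}
        for c in comps:
            olds = [r for r in alive if r in c]
            r_new = rep(c)
            if not olds:
                new_alive[r_new] = float(values[r_new])
            else:
                elder = min(olds, key=lambda r: (alive[r], r))
                for r in olds:
                    if r is not elder and alive[r] < h:
                        bars.append((alive[r], float(h)))
                new_alive[r_new] = alive[elder]
        alive = new_alive
    for r, b in alive.items():
        bars.append((b, math.inf))
    return sorted(bars)


def plain_reduction(simplices: dict[tuple[int, ...], float]):
    """Standard unoptimised persistence: global column reduction in
    filtration order.  Returns dict degree -> sorted list of (birth, death),
    zero-length bars dropped."""
    order = sorted(simplices, key=lambda s: (simplices[s], len(s), s))
    index = {s: i for i, s in enumerate(order)}
    columns = []
    for s in order:
        if len(s) == 1:
            columns.append(set())
        else:
            columns.append({index[s[:i] + s[i + 1 :]] for i in range(len(s))})
    lowinv: dict[int, int] = {}
    pairs = []
    for j in range(len(order)):
        col = columns[j]
        while col and max(col) in lowinv:
            col ^= columns[lowinv[max(col)]]
        columns[j] = col
        if col:
            lowinv[max(col)] = j
            pairs.append((max(col), j))
    paired = {p for pr in pairs for p in pr}
    out: dict[int, list] = {}
    for p, j in pairs:
        b, d = simplices[order[p]], simplices[order[j]]
        if b < d:
            out.setdefault(len(order[p]) - 1, []).append((b, d))
    for i in range(len(order)):
        if i not in paired:
            out.setdefault(len(order[i]) - 1, []).append((simplices[order[i]], math.inf))
    return {k: sorted(v) for k, v in out.items()}


def bottleneck_by_enumeration(a: list, b: list) -> float:
    """Exact bottleneck distance by enumerating all matchings (each bar may
    also go to the diagonal).  Exponential; only for tiny diagrams."""
    a, b = list(a), list(b)
    best = math.inf
    n, m = len(a), len(b)
    linf = lambda p, q: max(abs(p[0] - q[0]), abs(p[1] - q[1]))
    diag = lambda p: (p[1] - p[0]) / 2.0

    def rec(i, used, cur):
        nonlocal best
        if cur >= best:
            return
        if i == n:
            rest = max((diag(b[j]) for j in range(m) if j not in used), default=0.0)
            best = min(best, max(cur, rest))
            return
        rec(i + 1, used, max(cur, diag(a[i])))
        for j in range(m):
            if j not in used:
                rec(i + 1, used | {j}, max(cur, linf(a[i], b[j])))

    rec(0, frozenset(), 0.0)
    return best


def wasserstein_by_enumeration(a: list, b: list, order: float = 2.0) -> float:
    """Exact Wasserstein by enumerating all partial injections a -> b."""
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    linf = lambda p, q: max(abs(p[0] - q[0]), abs(p[1] - q[1]))
    diag = lambda p: (p[1] - p[0]) / 2.0
    best = math.inf
    idx_b = list(range(m))
    for k in range(0, min(n, m) + 1):
        for sub_a in itertools.combinations(range(n), k):
            for sub_b in itertools.permutations(idx_b, k):
                cost = 0.0
                for i, j in zip(sub_a, sub_b):
                    cost += linf(a[i], b[j]) ** order
                for i in set(range(n)) - set(sub_a):
                    cost += diag(a[i]) ** order
                for j in set(idx_b) - set(sub_b):
                    cost += diag(b[j]) ** order
                best = min(best, cost)
    return best ** (1.0 / order)


def local_minima_count(values: np.ndarray, edges: list[tuple[int, int]]) -> int:
    """Vertices whose value is strictly smaller than all neighbours'."""
    values = np.asarray(values, dtype=float)
    adj: dict[int, set[int]] = {i: set() for i in range(len(values))}
    for x, y in edges:
        adj[x].add(y)
        adj[y].add(x)
    return sum(
        1
        for i in range(len(values))
        if all(values[i] < values[j] for j in adj[i])
    )


def _kuhn_max_matching(adj: list[list[int]], n_right: int) -> int:
    """Maximum bipartite matching size by Kuhn's augmenting-path algorithm."""
    match_r = [-1] * n_right

    def try_augment(u: int, visited: list[bool]) -> bool:
        for v in adj[u]:
            if not visited[v]:
                visited[v] = True
                if match_r[v] == -1 or try_augment(match_r[v], visited):
                    match_r[v] = u
                    return True
        return False

    size = 0
    for u in range(len(adj)):
        if try_augment(u, [False] * n_right):
            size += 1
    return size


def bottleneck_by_threshold_search(a: list, b: list) -> float:
    """Exact bottleneck distance: smallest candidate cost t at which a
    perfect matching (bars may pair with the diagonal) exists, tested with
    an augmenting-path matcher.  Independent of the package's
    scipy-sparse-based feasibility test."""
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    if n == 0 and m == 0:
        return 0.0
    linf = lambda p, q: max(abs(p[0] - q[0]), abs(p[1] - q[1]))
    diag = lambda p: (p[1] - p[0]) / 2.0
    cands = sorted(
        {0.0}
        | {linf(p, q) for p in a for q in b}
        | {diag(p) for p in a}
        | {diag(q) for q in b}
    )

    def feasible(t: float) -> bool:
        # left: a-bars then m diagonal slots; right: b-bars then n diag slots
        adj = []
        for i, p in enumerate(a):
            row = [j for j, q in enumerate(b) if linf(p, q) <= t]
            if diag(p) <= t:
                row.append(m + i)
            adj.append(row)
        for j, q in enumerate(b):
            row = list(range(m, m + n))
            if diag(q) <= t:
                row.append(j)
            adj.append(row)
        return _kuhn_max_matching(adj, n + m) == n + m

    lo, hi = 0, len(cands) - 1
    if feasible(cands[0]):
        return cands[0]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if feasible(cands[mid]):
            hi = mid
        else:
            lo = mid
    return cands[hi]
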
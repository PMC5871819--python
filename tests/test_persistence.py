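"""Persistence core: sublevel degree-0 sweep, alpha complexes, reduction and
barcode distances, each validated against an independent brute-force oracle."""

import math

import numpy as np
import pytest

from airwaytopo import (
    AirwayTree,
    Barcode,
    FiltrationFunction,
    alpha_filtration,
    bottleneck_distance,
    persistence,
    read_diagram,
    sublevel_barcode_deg0,
    total_persistence,
    wasserstein_distance,
    write_diagram,
)
from airwaytopo.errors import DegenerateInputError, UnitMismatchError
from conftest import random_graph_tree
from oracles import (
    bottleneck_by_enumeration,
    local_minima_count,
    plain_reduction,
    sublevel_deg0_by_tracking,
    wasserstein_by_enumeration,
)


def _path_tree(values):
    n = len(values)
    t = AirwayTree(
        ids=np.arange(1, n + 1),
        positions=[[0, 0, -k] for k in range(n)],
        parent_ids=[-1] + list(range(1, n)),
    )
    f = FiltrationFunction({k + 1: float(v) for k, v in enumerate(values)})
    return t, f


class TestSublevelDeg0:
    def test_monotone_path_single_essential(self):
        t, f = _path_tree([0, 1, 2])
        assert sublevel_barcode_deg0(t, f).bars == ((0.0, math.inf),)

    def test_two_minima_merge_at_saddle(self):
        t, f = _path_tree([0, 2, 1])
        assert sublevel_barcode_deg0(t, f).bars == ((0.0, math.inf), (1.0, 2.0))

    def test_missing_vertex_value_rejected(self):
        t, _ = _path_tree([0, 1, 2])
        with pytest.raises(ValueError):
            sublevel_barcode_deg0(t, FiltrationFunction({1: 0.0}))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_component_tracking_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        tree = random_graph_tree(rng, n)
        vals = rng.permutation(n).astype(float)  # injective
        f = FiltrationFunction({int(i): vals[k] for k, i in enumerate(tree.ids)})
        got = sublevel_barcode_deg0(tree, f)
        edges = [tuple(e) for e in tree.edges()]
        expected = sublevel_deg0_by_tracking(vals, edges)
        assert sorted(got.bars) == expected
        # finite bars + components = local minima
        n_fin = len(got.finite())
        assert n_fin + got.n_infinite() == local_minima_count(vals, edges)

    @pytest.mark.parametrize("eps", [0.01, 0.1])
    def test_stability_under_value_perturbation(self, eps):
        rng = np.random.default_rng(5)
        tree = random_graph_tree(rng, 120)
        vals = rng.uniform(0, 10, tree.n_nodes)
        pert = vals + rng.uniform(-eps, eps, tree.n_nodes)
        f1 = FiltrationFunction({int(i): float(v) for i, v in zip(tree.ids, vals)})
        f2 = FiltrationFunction({int(i): float(v) for i, v in zip(tree.ids, pert)})
        b1 = sublevel_barcode_deg0(tree, f1).capped(12.0)
        b2 = sublevel_barcode_deg0(tree, f2).capped(12.0)
        assert bottleneck_distance(b1, b2) <= eps + 1e-12


class TestAlphaComplex:
    def test_two_points_edge_at_half_distance(self):
        cx = alpha_filtration([[0, 0, 0], [1, 0, 0]])
        assert cx.simplices[(0, 1)] == pytest.approx(0.5, rel=1e-4)

    def test_unit_square_values(self):
        cx = alpha_filtration(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], jitter_seed=3
        )
        edges = sorted(v for s, v in cx.simplices.items() if len(s) == 2)
        assert np.allclose(edges[:4], 0.5, atol=1e-3)
        assert edges[4] == pytest.approx(math.sqrt(2) / 2, abs=1e-3)
        tris = [v for s, v in cx.simplices.items() if len(s) == 3]
        assert np.allclose(tris, math.sqrt(2) / 2, atol=1e-3)

    def test_monotone_and_closed(self, rng):
        pts = rng.uniform(0, 20, size=(40, 3))
        cx = alpha_filtration(pts, jitter_seed=1)
        cx.validate()  # exhaustive face scan

    def test_all_identical_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            alpha_filtration([[1, 1, 1]] * 5)

    def test_scale_equivariance(self, rng):
        pts = rng.uniform(0, 10, size=(25, 3))
        b1 = persistence(alpha_filtration(pts, jitter_seed=2), 1)
        b2 = persistence(alpha_filtration(3.0 * pts, jitter_seed=2), 1)
        assert len(b1) == len(b2)
        for (a1, d1), (a2, d2) in zip(b1.bars, b2.bars):
            assert a2 == pytest.approx(3 * a1, rel=1e-3, abs=1e-6)
            assert d2 == pytest.approx(3 * d1, rel=1e-3, abs=1e-6)


class TestPersistenceReduction:
    def test_unit_square_deg1_bar(self):
        cx = alpha_filtration(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], jitter_seed=1
        )
        (bar,) = persistence(cx, 1).bars
        assert bar[0] == pytest.approx(0.5, abs=1e-3)
        assert bar[1] == pytest.approx(math.sqrt(2) / 2, abs=1e-3)

    def test_deg0_bar_count_equals_point_count(self, rng):
        pts = rng.uniform(0, 5, size=(30, 3))
        b0 = persistence(alpha_filtration(pts, jitter_seed=0), 0)
        assert len(b0) == 30
        assert all(b == 0.0 for b, _ in b0.bars)
        assert b0.n_infinite() == 1

    def test_sphere_limit_deg2(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(400, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        cx = alpha_filtration(10.0 * v, jitter_seed=0)
        b2 = persistence(cx, 2)
        dom = max(b2.bars, key=lambda bd: bd[1] - bd[0])
        assert abs(dom[1] - 10.0) < 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_plain_reduction_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 10, size=(int(rng.integers(8, 25)), 3))
        cx = alpha_filtration(pts, jitter_seed=seed)
        expected = plain_reduction(cx.simplices)
        for deg in (0, 1, 2):
            got = persistence(cx, deg)
            exp = sorted(expected.get(deg, []))
            assert len(got.bars) == len(exp)
            for g, e in zip(sorted(got.bars), exp):
                assert g == pytest.approx(e, rel=1e-9, abs=1e-12)

    def test_unsupported_degree(self):
        cx = alpha_filtration([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            persistence(cx, 3)


class TestDistances:
    def test_identity(self):
        b = Barcode(0, ((0.0, 1.0), (0.5, 2.0)), units="mm_depth")
        assert bottleneck_distance(b, b) == 0.0
        assert wasserstein_distance(b, b) == 0.0

    def test_single_bar_to_empty(self):
        b = Barcode(0, ((0.0, 10.0),), units="mm_depth")
        e = Barcode(0, (), units="mm_depth")
        assert bottleneck_distance(b, e) == pytest.approx(5.0)
        b2 = Barcode(0, ((0.0, 2.0),), units="mm_depth")
        assert wasserstein_distance(b2, e) == pytest.approx(1.0)

    def test_unit_mismatch_rejected(self):
        a = Barcode(0, (), units="mm_depth")
        b = Barcode(0, (), units="mm_radius")
        with pytest.raises(UnitMismatchError):
            bottleneck_distance(a, b)
        with pytest.raises(UnitMismatchError):
            wasserstein_distance(a, Barcode(1, (), units="mm_depth"))

    @pytest.mark.parametrize("seed", range(6))
    def test_small_diagrams_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        def diag(k):
            b = rng.uniform(0, 5, k)
            return tuple((float(x), float(x + rng.uniform(0.1, 4))) for x in b)
        a = Barcode(1, diag(int(rng.integers(0, 6))), units="mm_radius")
        b = Barcode(1, diag(int(rng.integers(0, 6))), units="mm_radius")
        assert bottleneck_distance(a, b) == pytest.approx(
            bottleneck_by_enumeration(a.bars, b.bars), rel=1e-12, abs=1e-12
        )
        assert wasserstein_distance(a, b) == pytest.approx(
            wasserstein_by_enumeration(a.bars, b.bars), rel=1e-9
        )

    def test_metric_axioms_on_random_diagrams(self):
        rng = np.random.default_rng(99)
        diags = []
        for _ in range(5):
            b = rng.uniform(0, 5, 12)
            diags.append(
                Barcode(
                    1,
                    tuple((float(x), float(x + rng.uniform(0.05, 3))) for x in b),
                    units="mm_radius",
                )
            )
        for metric in (bottleneck_distance, wasserstein_distance):
            d = [[metric(a, b) for b in diags] for a in diags]
            for i in range(5):
                assert d[i][i] == 0.0
                for j in range(5):
                    assert d[i][j] >= 0
                    assert d[i][j] == pytest.approx(d[j][i], rel=1e-9)
                    for k in range(5):
                        assert d[i][j] <= d[i][k] + d[k][j] + 1e-9


class TestTotalPersistence:
    def test_values_and_additivity(self):
        assert total_persistence(Barcode(1, ())) == 0.0
        b = Barcode(1, ((0.5, 0.7071),))
        assert total_persistence(b) == pytest.approx(0.2071)
        c = Barcode(1, ((0.5, 0.7071), (1.0, 2.0)))
        assert total_persistence(c) == pytest.approx(
            total_persistence(b) + total_persistence(Barcode(1, ((1.0, 2.0),)))
        )

    def test_requires_capping(self):
        b = Barcode(0, ((0.0, math.inf),), fmax=4.0)
        with pytest.raises(ValueError):
            total_persistence(b)
        assert b.capped().total_persistence() == pytest.approx(4.0)


class TestDiagramIO:
    def test_round_trip(self, tmp_path, rng):
        bars = tuple(
            (float(b), float(b + d))
            for b, d in zip(rng.uniform(0, 5, 10), rng.uniform(0.1, 3, 10))
        )
        bc = Barcode(2, bars + ((0.0, math.inf),), units="mm_radius", fmax=9.0)
        p = tmp_path / "d.dgm"
        write_diagram(bc, p)
        back = read_diagram(p)
        assert back == bc

    def test_empty_with_header(self, tmp_path):
        p = tmp_path / "e.dgm"
        p.write_text("# degree: 1\n# units: mm_radius\n")
        bc = read_diagram(p)
        assert bc.degree == 1 and len(bc) == 0

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "bad.dgm"
        p.write_text("# degree: 0\n0.0 1.0\noops\n")
        with pytest.raises(ValueError, match=":3"):
            read_diagram(p)
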
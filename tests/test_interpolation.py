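"""Scattered-data interpolation: exactness, weights, limits and dispatch."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from spectra_emu import (
    IDWConfig,
    InterpolationModel,
    barycentric_coordinates,
    hybrid_predict,
    idw_predict,
    idw_weights,
    linear_predict,
    nearest_predict,
)


def _random_model(rng, m=50, d=3, k=5, method="linear", idw_config=None):
    X = rng.uniform(0, 10, (m, d))
    Y = rng.uniform(0, 1, (m, k))
    return InterpolationModel(X, Y, method=method, idw_config=idw_config)


class TestNearest:
    def test_single_node(self):
        model = InterpolationModel([[1.0, 2.0]], [[0.3, 0.4]], method="nearest")
        pred = nearest_predict(model, [[5.0, 5.0], [0.0, 0.0]])
        assert np.array_equal(pred, [[0.3, 0.4], [0.3, 0.4]])

    def test_one_dimensional(self):
        model = InterpolationModel([[0.0], [10.0]], [[1.0], [2.0]], method="nearest")
        assert nearest_predict(model, [[3.0]])[0, 0] == 1.0

    def test_tie_breaks_to_lowest_index(self):
        model = InterpolationModel([[0.0], [10.0]], [[1.0], [2.0]], method="nearest")
        assert nearest_predict(model, [[5.0]])[0, 0] == 1.0


class TestBarycentric:
    def test_at_vertex(self):
        V = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        w = barycentric_coordinates(V, V[0]).weights
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0], atol=1e-12)

    def test_at_centroid(self):
        V = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
        w = barycentric_coordinates(V, V.mean(axis=0)).weights
        np.testing.assert_allclose(w, [1 / 3] * 3, atol=1e-12)

    def test_one_dimensional_segment(self):
        w = barycentric_coordinates(np.array([[0.0], [1.0]]), np.array([0.25])).weights
        np.testing.assert_allclose(w, [0.75, 0.25], atol=1e-12)

    def test_degenerate_simplex_raises(self):
        V = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # collinear
        with pytest.raises(ValueError, match="degenerate"):
            barycentric_coordinates(V, np.array([0.5, 0.5]))

    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_reproduces_query_and_sums_to_one(self, d):
        rng = np.random.default_rng(d)
        V = rng.uniform(-1, 1, (d + 1, d))
        x = rng.uniform(-1, 1, d)
        bw = barycentric_coordinates(V, x)
        assert abs(bw.weights.sum() - 1.0) < 1e-10
        np.testing.assert_allclose(bw.weights @ V, x, atol=1e-9)


class TestLinear:
    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_exact_on_affine_functions(self, d):
        """Piece-wise linear interpolation reproduces affine maps exactly."""
        rng = np.random.default_rng(10 + d)
        X = rng.uniform(0, 1, (50, d))
        A = rng.uniform(-2, 2, (d, 3))
        c = rng.uniform(-1, 1, 3)
        model = InterpolationModel(X, X @ A + c, method="linear")
        # interior queries: convex combinations of node subsets
        w = rng.dirichlet(np.ones(50), size=100)
        Xq = w @ X
        pred, inside = linear_predict(model, Xq)
        assert inside.all()
        np.testing.assert_allclose(pred, Xq @ A + c, rtol=1e-9, atol=1e-9)

    def test_query_at_node_returns_node_value(self):
        rng = np.random.default_rng(2)
        model = _random_model(rng, m=30, d=2)
        pred, inside = linear_predict(model, model.nodes_X[:5])
        assert inside.all()
        np.testing.assert_allclose(pred, model.nodes_Y[:5], atol=1e-9)

    def test_outside_hull_flagged_nan(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        model = InterpolationModel(X, np.ones((4, 2)), method="linear")
        pred, inside = linear_predict(model, [[5.0, 5.0]])
        assert not inside[0]
        assert np.isnan(pred[0]).all()

    def test_agrees_with_brute_force_simplex_oracle(self):
        """Cross-check against exhaustive simplex-containment search."""
        rng = np.random.default_rng(5)
        m, d, k = 25, 2, 3
        model = _random_model(rng, m=m, d=d, k=k)
        tri = Delaunay(model._scaled_nodes)
        Xq = rng.uniform(2, 8, (40, d))
        pred, inside = linear_predict(model, Xq)
        S = model.scale_queries(Xq)
        for q in range(40):
            expected = None
            for simplex in tri.simplices:
                bw = barycentric_coordinates(tri.points[simplex], S[q])
                if np.all(bw.weights >= -1e-10):
                    expected = bw.weights @ model.nodes_Y[simplex]
                    break
            if expected is None:
                assert not inside[q]
            else:
                assert inside[q]
                np.testing.assert_allclose(pred[q], expected, atol=1e-9)

    def test_convexity_per_band(self):
        rng = np.random.default_rng(8)
        model = _random_model(rng, m=40, d=3)
        w = rng.dirichlet(np.ones(40), size=50)
        pred, inside = linear_predict(model, w @ model.nodes_X)
        assert inside.all()
        assert np.all(pred <= model.nodes_Y.max(axis=0) + 1e-12)
        assert np.all(pred >= model.nodes_Y.min(axis=0) - 1e-12)

    def test_degenerate_nodes_raise_with_idw_hint(self):
        model = InterpolationModel(
            [[0.0, 0.0], [1.0, 1.0]], [[0.1], [0.2]], method="linear"
        )
        with pytest.raises(Exception, match="IDW"):
            linear_predict(model, [[0.5, 0.5]])


class TestIDWWeights:
    def test_basic_weights_inverse_square(self):
        # nodes at 0 and 1 span the unit interval, so scaling is identity
        # and a query at -1 sits at distances (1, 2) from the nodes
        model = InterpolationModel(
            [[0.0], [1.0]], [[1.0], [0.0]],
            method="idw", idw_config=IDWConfig(p=2.0, n_neighbors=2, variant="basic"),
        )
        nw = idw_weights(model, [-1.0])
        np.testing.assert_allclose(nw.distances, [1.0, 2.0])
        np.testing.assert_allclose(nw.weights, [1.0, 0.25])

    def test_modified_shepard_weights(self):
        # distances (1, 2) -> R = 2; weight at d=1 is ((2-1)/(2*1))^2 = 0.25
        model = InterpolationModel(
            [[0.0], [1.0]], [[1.0], [0.0]],
            method="idw",
            idw_config=IDWConfig(p=2.0, n_neighbors=2, variant="modified_shepard"),
        )
        nw = idw_weights(model, [-1.0])
        assert nw.R == 2.0
        np.testing.assert_allclose(nw.weights, [0.25, 0.0])

    def test_node_hit_gives_one_hot(self):
        model = InterpolationModel(
            [[0.0], [1.0]], [[1.0], [0.0]],
            method="idw", idw_config=IDWConfig(p=2.0, n_neighbors=2),
        )
        nw = idw_weights(model, [0.0])
        np.testing.assert_array_equal(nw.weights, [1.0, 0.0])
        assert nw.indices[0] == 0


class TestIDWPredict:
    def test_midpoint_symmetry(self):
        model = InterpolationModel(
            [[0.0], [1.0]], [[0.0], [1.0]],
            method="idw", idw_config=IDWConfig(p=2.0, n_neighbors=2, variant="basic"),
        )
        assert idw_predict(model, [[0.5]])[0, 0] == pytest.approx(0.5)

    def test_node_query_returns_node_spectrum(self):
        rng = np.random.default_rng(3)
        model = _random_model(rng, m=20, d=3, method="idw")
        pred = idw_predict(model, model.nodes_X[:4])
        np.testing.assert_array_equal(pred, model.nodes_Y[:4])

    @pytest.mark.parametrize("variant", ["basic", "modified_shepard"])
    def test_convexity(self, variant):
        rng = np.random.default_rng(4)
        model = _random_model(
            rng, m=20, d=3, method="idw",
            idw_config=IDWConfig(p=2.0, n_neighbors=5, variant=variant),
        )
        pred = idw_predict(model, rng.uniform(-2, 12, (30, 3)))
        assert np.all(pred <= model.nodes_Y.max(axis=0) + 1e-12)
        assert np.all(pred >= model.nodes_Y.min(axis=0) - 1e-12)

    def test_large_power_limit_is_nearest_neighbour(self):
        """As p grows, IDW collapses onto nearest-neighbour interpolation.

        Random queries sitting almost exactly between two nodes have not
        converged to the limit at any finite p, so queries are rejection
        sampled until the two nearest nodes are clearly separated (ratio
        >= 1.2, at which point the non-nearest weight underflows).
        """
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 10, (20, 3))
        Y = rng.uniform(0, 1, (20, 4))
        idw = InterpolationModel(
            X, Y, method="idw",
            idw_config=IDWConfig(p=200.0, n_neighbors=10, variant="basic"),
        )
        nn = InterpolationModel(X, Y, method="nearest")
        queries = []
        while len(queries) < 50:
            q = rng.uniform(0, 10, 3)
            d = np.sort(np.linalg.norm(idw.scale_queries(q[None])[0]
                                       - idw._scaled_nodes, axis=1))
            if d[1] >= 1.2 * d[0]:
                queries.append(q)
        Xq = np.array(queries)
        np.testing.assert_allclose(
            idw_predict(idw, Xq), nearest_predict(nn, Xq), rtol=1e-12, atol=1e-12
        )


class TestHybrid:
    def test_interior_matches_linear(self):
        rng = np.random.default_rng(7)
        model = _random_model(rng, m=40, d=3, method="linear_idw")
        w = rng.dirichlet(np.ones(40), size=20)
        Xq = w @ model.nodes_X
        expected, inside = linear_predict(model, Xq)
        assert inside.all()
        np.testing.assert_array_equal(hybrid_predict(model, Xq), expected)

    def test_exterior_matches_idw(self):
        rng = np.random.default_rng(9)
        model = _random_model(rng, m=40, d=3, method="linear_idw")
        Xq = model.nodes_X.max(axis=0) + rng.uniform(1, 5, (10, 3))
        np.testing.assert_array_equal(
            hybrid_predict(model, Xq), idw_predict(model, Xq)
        )

    def test_mixed_batch_row_wise_dispatch(self):
        rng = np.random.default_rng(11)
        model = _random_model(rng, m=40, d=3, method="linear_idw")
        w = rng.dirichlet(np.ones(40), size=10)
        Xq = np.vstack([w @ model.nodes_X, model.nodes_X.max(axis=0) + 2.0])
        pred = hybrid_predict(model, Xq)
        _, inside = linear_predict(model, Xq)
        lin, _ = linear_predict(model, Xq[inside])
        np.testing.assert_array_equal(pred[inside], lin)
        np.testing.assert_array_equal(pred[~inside], idw_predict(model, Xq[~inside]))
        assert np.isfinite(pred).all()

    def test_degenerate_triangulation_falls_back_to_idw(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])  # collinear in 2-D
        Y = np.array([[0.1], [0.2], [0.3]])
        model = InterpolationModel(X, Y, method="linear_idw")
        with pytest.warns(UserWarning, match="IDW"):
            pred = hybrid_predict(model, [[0.5, 0.5]])
        assert np.isfinite(pred).all()
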
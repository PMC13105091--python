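import numpy as np
import pytest
import scipy.linalg
import scipy.optimize

from lorax.data_model import RepresentationMatrix, ValidationError
from lorax.shape_metrics import (
    align_and_center,
    cca_distance,
    pairwise_distances,
    procrustes_distance,
)


def _rep(values, name="r", ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    return RepresentationMatrix(ids, values, name)


def _rand_rep(rng, n, d, name="r"):
    return _rep(rng.standard_normal((n, d)), name)


def _rotation(rng, d):
    q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Independent oracles


def brute_force_procrustes_2d(Xn, Yn):
    """Best-alignment trace over O(2) by dense angle scan (no SVD)."""
    C = Xn.T @ Yn
    thetas = np.linspace(0, 2 * np.pi, 400_001)
    c, s = np.cos(thetas), np.sin(thetas)
    # rotations [[c,-s],[s,c]] and reflections [[c,s],[s,-c]]
    tr_rot = (C[0, 0] + C[1, 1]) * c + (C[1, 0] - C[0, 1]) * s
    tr_ref = (C[0, 0] - C[1, 1]) * c + (C[1, 0] + C[0, 1]) * s
    best = max(tr_rot.max(), tr_ref.max())
    return np.arccos(np.clip(best, 0.0, 1.0))


def brute_force_procrustes_od(Xn, Yn, seed=0):
    """Maximize trace(Q^T X^T Y) over O(d) by multistart optimization on
    skew-symmetric exponential coordinates, for both determinant signs."""
    d = Xn.shape[1]
    C = Xn.T @ Yn
    rng = np.random.default_rng(seed)
    k = d * (d - 1) // 2
    iu = np.triu_indices(d, 1)

    def q_from(params, flip):
        S = np.zeros((d, d))
        S[iu] = params
        S -= S.T
        Q = scipy.linalg.expm(S)
        if flip:
            F = np.eye(d)
            F[0, 0] = -1
            Q = Q @ F
        return Q

    best = -np.inf
    for flip in (False, True):
        for _ in range(12):
            x0 = rng.uniform(-np.pi, np.pi, size=k)
            res = scipy.optimize.minimize(
                lambda p: -np.trace(q_from(p, flip).T @ C), x0, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
            )
            best = max(best, -res.fun)
    return np.arccos(np.clip(best, 0.0, 1.0))


def cca_correlations_oracle(X, Y):
    """Canonical correlations via the classical generalized-eigen approach."""
    X = X - X.mean(0)
    Y = Y - Y.mean(0)
    qx, _ = np.linalg.qr(X)
    qy, _ = np.linalg.qr(Y)
    return np.clip(np.linalg.svd(qx.T @ qy, compute_uv=False), 0, 1)


# ---------------------------------------------------------------------------


class TestAlignAndCenter:
    def test_reorders_to_common_items(self):
        X = _rep(np.arange(6).reshape(3, 2), ids=["a", "b", "c"])
        Y = _rep(np.arange(6).reshape(3, 2)[::-1], ids=["c", "a", "b"])
        Xc, Yc = align_and_center(X, Y)
        # Y reordered to (a, b, c): row for 'a' is original Y row 1 -> [2, 3]
        assert np.allclose(Yc, np.array([[2, 3], [0, 1], [4, 5]]) - [2, 3])

    def test_columns_centered(self):
        X = _rep([[1.0], [2.0], [3.0]])
        Xc, _ = align_and_center(X, X)
        assert np.allclose(Xc[:, 0], [-1, 0, 1])

    def test_zero_padding_to_common_width(self, rng):
        X = _rand_rep(rng, 5, 3)
        Y = _rep(rng.standard_normal((5, 5)), ids=X.item_ids)
        Xc, Yc = align_and_center(X, Y)
        assert Xc.shape == Yc.shape == (5, 5)
        assert np.all(Xc[:, 3:] == 0)

    def test_item_mismatch_lists_difference(self):
        X = _rep(np.eye(3), ids=["a", "b", "c"])
        Y = _rep(np.eye(3), ids=["a", "b", "d"])
        with pytest.raises(ValidationError, match="c.*d|d.*c"):
            align_and_center(X, Y)


class TestProcrustes:
    def test_self_distance_zero(self, rng):
        X = _rand_rep(rng, 8, 3)
        assert procrustes_distance(X, X).value == 0.0

    def test_rotation_and_scale_invariance(self, rng):
        X = _rand_rep(rng, 10, 4)
        R = _rotation(rng, 4)
        Y = _rep(2.0 * X.values @ R, ids=X.item_ids)
        assert procrustes_distance(X, Y).value == pytest.approx(0.0, abs=1e-7)

    def test_worked_example_pi_over_3(self):
        X = _rep([[1, 0], [-1, 0], [0, 0]])
        Y = _rep([[1, 0], [0, 0], [-1, 0]])
        d = procrustes_distance(X, Y)
        assert d.value == pytest.approx(np.arccos(0.5), abs=1e-8)
        # independent dense-scan oracle over O(2)
        Xc, Yc = align_and_center(X, Y)
        Xn, Yn = Xc / np.linalg.norm(Xc), Yc / np.linalg.norm(Yc)
        assert brute_force_procrustes_2d(Xn, Yn) == pytest.approx(d.value, abs=1e-6)

    def test_anisotropic_scaling_moves_distance(self, rng):
        X = _rand_rep(rng, 12, 2)
        Y = _rep(X.values @ np.diag([1.0, 10.0]), ids=X.item_ids)
        assert procrustes_distance(X, Y).value > 1e-3

    def test_matches_brute_force_over_od(self, rng):
        for d in (2, 3):
            for _ in range(3):
                X = _rand_rep(rng, 8, d)
                Y = _rep(rng.standard_normal((8, d)), ids=X.item_ids)
                got = procrustes_distance(X, Y).value
                Xc, Yc = align_and_center(X, Y)
                Xn = Xc / np.linalg.norm(Xc)
                Yn = Yc / np.linalg.norm(Yc)
                oracle = brute_force_procrustes_od(Xn, Yn)
                assert got == pytest.approx(oracle, abs=1e-6)

    def test_zero_matrix_errors(self):
        X = _rep(np.zeros((4, 2)))
        with pytest.raises(ValidationError, match="zero"):
            procrustes_distance(X, X)


class TestCCA:
    def test_self_distance_zero(self, rng):
        X = _rand_rep(rng, 9, 3)
        assert cca_distance(X, X).value == pytest.approx(0.0, abs=1e-7)

    def test_invertible_linear_invariance(self, rng):
        X = _rand_rep(rng, 15, 4)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        Y = _rep(X.values @ A, ids=X.item_ids)
        assert cca_distance(X, Y).value == pytest.approx(0.0, abs=1e-6)

    def test_cca_zero_where_procrustes_positive(self, rng):
        X = _rand_rep(rng, 15, 3)
        A = np.diag([1.0, 5.0, 0.2]) @ (rng.standard_normal((3, 3)) + 3 * np.eye(3))
        Y = _rep(X.values @ A, ids=X.item_ids)
        assert cca_distance(X, Y).value < 1e-6
        assert procrustes_distance(X, Y).value > 1e-3

    def test_orthogonal_subspaces_give_right_angle(self):
        # column spaces occupy disjoint item blocks: X varies only over the
        # first half of the items, Y only over the second half, each column
        # already zero-mean so centering preserves the orthogonality
        n = 12
        X = np.zeros((n, 2))
        X[0:3, 0] = [1, -1, 0]
        X[2:5, 1] = [1, 0, -1]
        Y = np.zeros((n, 2))
        Y[6:9, 0] = [1, -1, 0]
        Y[8:11, 1] = [1, 0, -1]
        ids = [f"i{k}" for k in range(n)]
        d = cca_distance(_rep(X, ids=ids), _rep(Y, ids=ids))
        assert d.value == pytest.approx(np.pi / 2, abs=1e-6)
        assert np.all(d.rho < 1e-8)
        # independent canonical-correlation solver agrees
        assert np.allclose(cca_correlations_oracle(X, Y), 0, atol=1e-8)

    def test_correlations_match_oracle(self, rng):
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 4))
        ids = [f"i{k}" for k in range(20)]
        d = cca_distance(_rep(X, ids=ids), _rep(Y, ids=ids))
        oracle = np.sort(cca_correlations_oracle(X, Y))[::-1]
        assert np.allclose(np.sort(d.rho)[::-1][: len(oracle)], oracle, atol=1e-8)

    def test_rho_sorted_descending(self, rng):
        X = _rand_rep(rng, 18, 4)
        Y = _rep(np.random.default_rng(1).standard_normal((18, 4)), ids=X.item_ids)
        d = cca_distance(X, Y)
        assert np.all(np.diff(d.rho) <= 1e-12)

    def test_constant_matrix_errors(self):
        X = _rep(np.ones((5, 2)))
        with pytest.raises(ValidationError, match="rank 0"):
            cca_distance(X, X)


class TestMetricAxioms:
    @pytest.mark.parametrize("metric", ["procrustes", "cca"])
    def test_symmetry_and_nonnegativity(self, metric, rng):
        fn = procrustes_distance if metric == "procrustes" else cca_distance
        for _ in range(20):
            n, d1, d2 = rng.integers(5, 15), rng.integers(2, 5), rng.integers(2, 5)
            ids = [f"i{k}" for k in range(n)]
            X = _rep(rng.standard_normal((n, d1)), ids=ids)
            Y = _rep(rng.standard_normal((n, d2)), ids=ids)
            dxy, dyx = fn(X, Y).value, fn(Y, X).value
            assert dxy >= 0
            assert abs(dxy - dyx) <= 1e-8

    @pytest.mark.parametrize("metric", ["procrustes", "cca"])
    def test_triangle_inequality_on_random_triples(self, metric):
        fn = procrustes_distance if metric == "procrustes" else cca_distance
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(8, 21))
            ids = [f"i{k}" for k in range(n)]
            reps = [
                _rep(rng.standard_normal((n, int(rng.integers(2, 7)))), ids=ids)
                for _ in range(3)
            ]
            dab = fn(reps[0], reps[1]).value
            dbc = fn(reps[1], reps[2]).value
            dac = fn(reps[0], reps[2]).value
            assert dac <= dab + dbc + 1e-6


class TestPairwise:
    def test_duplicate_representation_zero_block(self, rng):
        X = _rand_rep(rng, 8, 3, "x")
        dm = pairwise_distances([X, _rep(X.values, "x2", ids=X.item_ids)])
        assert np.allclose(dm.values, 0)

    def test_symmetric_zero_diagonal(self, rng):
        ids = [f"i{k}" for k in range(10)]
        reps = [_rep(rng.standard_normal((10, 3)), f"r{j}", ids) for j in range(3)]
        dm = pairwise_distances(reps, metric="cca")
        assert np.allclose(dm.values, dm.values.T, atol=1e-8)
        assert np.allclose(np.diag(dm.values), 0)

    def test_rotation_invariance_inside_matrix(self, rng):
        X = _rand_rep(rng, 10, 3, "x")
        R = _rotation(rng, 3)
        XR = _rep(X.values @ R, "xr", ids=X.item_ids)
        Z = _rep(rng.standard_normal((10, 3)), "z", ids=X.item_ids)
        dm = pairwise_distances([X, XR, Z], metric="procrustes")
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-7)
        assert dm.values[0, 2] == pytest.approx(dm.values[1, 2], abs=1e-7)
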
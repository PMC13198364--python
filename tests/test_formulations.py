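"""The unified BCD driver and its reductions to GW / UGW / COOT / UCOOT / AGW."""

import numpy as np
import pytest

from otalign.formulations import (
    AlignmentResult,
    SolverConfig,
    _fixed_block_offset,
    align,
    coupling_density,
    local_cost_coot,
    local_cost_gw,
    solve_uagw,
)
from otalign.geometry import DistanceMatrix, knn_geodesic, normalize_distances
from otalign.ot_core import INF, Coupling, DimensionError, LocalProblem, Marginal, solve_local
from otalign.synthetic import make_multiomic


def naive_gw_cost(DX, DY, T):
    nx, ny = T.shape
    C = np.zeros((nx, ny))
    for i in range(nx):
        for k in range(ny):
            for j in range(nx):
                for l in range(ny):
                    C[i, k] += (DX[i, j] - DY[k, l]) ** 2 * T[j, l]
    return C


def naive_coot_cost_samples(X, Y, Q):
    nx, ny = X.shape[0], Y.shape[0]
    C = np.zeros((nx, ny))
    for i in range(nx):
        for k in range(ny):
            for j in range(X.shape[1]):
                for l in range(Y.shape[1]):
                    C[i, k] += (X[i, j] - Y[k, l]) ** 2 * Q[j, l]
    return C


def naive_coot_cost_features(X, Y, P):
    dx, dy = X.shape[1], Y.shape[1]
    C = np.zeros((dx, dy))
    for j in range(dx):
        for l in range(dy):
            for i in range(X.shape[0]):
                for k in range(Y.shape[0]):
                    C[j, l] += (X[i, j] - Y[k, l]) ** 2 * P[i, k]
    return C


def random_distance_matrix(rng, n):
    pts = rng.random((n, 2))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return DistanceMatrix(D)


class TestLocalCosts:
    def test_gw_zero_distances(self):
        DX = DistanceMatrix(np.zeros((3, 3)))
        DY = DistanceMatrix(np.zeros((4, 4)))
        C = local_cost_gw(DX, DY, Coupling(np.full((3, 4), 1 / 12)))
        assert np.allclose(C, 0.0)

    def test_gw_matched_geometry_zero_diagonal(self, rng):
        D = random_distance_matrix(rng, 4)
        C = local_cost_gw(D, D, Coupling(np.eye(4) / 4))
        assert np.allclose(np.diag(C), 0.0, atol=1e-12)

    def test_gw_matches_naive_tensor(self, rng):
        DX = random_distance_matrix(rng, 3)
        DY = random_distance_matrix(rng, 4)
        T = rng.random((3, 4))
        C = local_cost_gw(DX, DY, Coupling(T))
        assert np.allclose(C, naive_gw_cost(DX.values, DY.values, T), atol=1e-10)

    def test_gw_shape_mismatch(self, rng):
        DX = random_distance_matrix(rng, 3)
        DY = random_distance_matrix(rng, 4)
        with pytest.raises(DimensionError):
            local_cost_gw(DX, DY, Coupling(np.ones((4, 3))))

    def test_coot_identical_data_zero_diagonal(self, rng):
        X = rng.random((4, 3))
        C = local_cost_coot(X, X, Coupling(np.eye(3) / 3), axis="samples")
        assert np.allclose(np.diag(C), 0.0, atol=1e-12)

    def test_coot_constant_matrices(self):
        X = np.full((3, 2), 1.7)
        Y = np.full((4, 3), 1.7)
        C = local_cost_coot(X, Y, Coupling(np.full((2, 3), 1 / 6)), axis="samples")
        assert np.allclose(C, 0.0)

    def test_coot_matches_naive_both_axes(self, rng):
        X = rng.random((3, 2))
        Y = rng.random((4, 3))
        Q = rng.random((2, 3))
        P = rng.random((3, 4))
        assert np.allclose(
            local_cost_coot(X, Y, Coupling(Q), axis="samples"),
            naive_coot_cost_samples(X, Y, Q),
            atol=1e-10,
        )
        assert np.allclose(
            local_cost_coot(X, Y, Coupling(P), axis="features"),
            naive_coot_cost_features(X, Y, P),
            atol=1e-10,
        )


def reference_gw(DX, DY, mu1, mu2, eps, rho1, rho2, n_outer, inner_max_iter, inner_tol):
    """Dedicated (U)GW BCD written without the generic alpha-blending driver."""
    P = Coupling(np.outer(mu1.weights, mu2.weights))
    Pp = Coupling(np.outer(mu1.weights, mu2.weights))
    warm = {"P": None, "Pp": None}
    trace = []
    for _ in range(n_outer):
        for name in ("P", "Pp"):
            fixed = Pp if name == "P" else P
            cost = local_cost_gw(DX, DY, fixed) + _fixed_block_offset(
                eps, rho1, rho2, fixed, mu1, mu2
            )
            m = fixed.total_mass
            prob = LocalProblem(
                cost=cost,
                mu1=mu1,
                mu2=mu2,
                epsilon=eps * m,
                rho1=rho1 * m if np.isfinite(rho1) else INF,
                rho2=rho2 * m if np.isfinite(rho2) else INF,
            )
            sol = solve_local(prob, max_iter=inner_max_iter, tol=inner_tol, warm_start=warm[name])
            warm[name] = (sol.f, sol.g)
            if name == "P":
                P = sol.coupling
            else:
                Pp = sol.coupling
        from otalign.formulations import _term_objective

        trace.append(
            _term_objective(
                local_cost_gw(DX, DY, Pp), P, eps, rho1, rho2, Pp, mu1, mu2, mu1, mu2
            )
        )
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < inner_tol:
            break
    return P, Pp


def reference_coot(X, Y, mus1, mus2, muf1, muf2, eps, rho1, rho2, n_outer, inner_max_iter, inner_tol):
    """Dedicated (U)COOT BCD written without the generic driver."""
    from otalign.formulations import _term_objective

    P = Coupling(np.outer(mus1.weights, mus2.weights))
    Q = Coupling(np.outer(muf1.weights, muf2.weights))
    warm = {"P": None, "Q": None}
    trace = []
    for _ in range(n_outer):
        for name in ("P", "Q"):
            if name == "P":
                fixed, axis, m1, m2, r1, r2 = Q, "samples", mus1, mus2, muf1, muf2
            else:
                fixed, axis, m1, m2, r1, r2 = P, "features", muf1, muf2, mus1, mus2
            cost = local_cost_coot(X, Y, fixed, axis=axis) + _fixed_block_offset(
                eps, rho1, rho2, fixed, r1, r2
            )
            m = fixed.total_mass
            prob = LocalProblem(
                cost=cost,
                mu1=m1,
                mu2=m2,
                epsilon=eps * m,
                rho1=rho1 * m if np.isfinite(rho1) else INF,
                rho2=rho2 * m if np.isfinite(rho2) else INF,
            )
            sol = solve_local(prob, max_iter=inner_max_iter, tol=inner_tol, warm_start=warm[name])
            warm[name] = (sol.f, sol.g)
            if name == "P":
                P = sol.coupling
            else:
                Q = sol.coupling
        trace.append(
            _term_objective(
                local_cost_coot(X, Y, Q, axis="samples"),
                P, eps, rho1, rho2, Q, mus1, mus2, muf1, muf2,
            )
        )
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < inner_tol:
            break
    return P, Q


@pytest.fixture
def instance_10(rng):
    DX = random_distance_matrix(rng, 10)
    DY = random_distance_matrix(rng, 10)
    X = rng.random((10, 6))
    Y = rng.random((10, 7))
    return X, Y, DX, DY


class TestReductions:
    @pytest.mark.parametrize("rho", [INF, 0.5])
    def test_alpha_one_reduces_to_gw(self, instance_10, rho):
        X, Y, DX, DY = instance_10
        mu = Marginal.uniform(10)
        cfg = SolverConfig(
            alpha=1.0, eps_gw=0.01, rho_gw1=rho, rho_gw2=rho, n_outer=10,
            inner_max_iter=2000, inner_tol=1e-9,
        )
        res = solve_uagw(None, None, DX, DY, mu, mu, None, None, cfg)
        P_ref, Pp_ref = reference_gw(DX, DY, mu, mu, 0.01, rho, rho, 10, 2000, 1e-9)
        assert np.allclose(res.P.plan, P_ref.plan, atol=1e-8)
        assert np.allclose(res.P_prime.plan, Pp_ref.plan, atol=1e-8)
        assert res.Q is None

    @pytest.mark.parametrize("rho", [INF, 0.5])
    def test_alpha_zero_reduces_to_coot(self, instance_10, rho):
        X, Y, DX, DY = instance_10
        mus = Marginal.uniform(10)
        muf1, muf2 = Marginal.uniform(6), Marginal.uniform(7)
        cfg = SolverConfig(
            alpha=0.0, eps_coot=0.01, rho_coot1=rho, rho_coot2=rho, n_outer=10,
            inner_max_iter=2000, inner_tol=1e-9,
        )
        res = solve_uagw(X, Y, None, None, mus, mus, muf1, muf2, cfg)
        P_ref, Q_ref = reference_coot(X, Y, mus, mus, muf1, muf2, 0.01, rho, rho, 10, 2000, 1e-9)
        assert np.allclose(res.P.plan, P_ref.plan, atol=1e-8)
        assert np.allclose(res.Q.plan, Q_ref.plan, atol=1e-8)


class TestSolverProperties:
    def test_balanced_mass_conservation(self, instance_10):
        X, Y, DX, DY = instance_10
        mu = Marginal.uniform(10)
        cfg = SolverConfig(alpha=0.5, eps_gw=0.01, eps_coot=0.01, n_outer=8)
        res = solve_uagw(X, Y, DX, DY, mu, mu, None, None, cfg)
        assert res.P.total_mass == pytest.approx(1.0, abs=1e-8)
        assert res.P_prime.total_mass == pytest.approx(1.0, abs=1e-8)
        assert res.Q.total_mass == pytest.approx(1.0, abs=1e-8)

    def test_loss_trace_non_increasing(self, rng):
        for _ in range(3):
            DX = random_distance_matrix(rng, 8)
            DY = random_distance_matrix(rng, 9)
            X = rng.random((8, 4))
            Y = rng.random((9, 5))
            cfg = SolverConfig(
                alpha=float(rng.uniform(0.2, 0.8)), eps_gw=0.02, eps_coot=0.02,
                rho_gw1=0.5, rho_gw2=0.5, rho_coot1=0.5, rho_coot2=0.5, n_outer=10,
            )
            res = solve_uagw(
                X, Y, DX, DY, Marginal.uniform(8), Marginal.uniform(9), None, None, cfg
            )
            diffs = np.diff(res.loss_trace)
            assert np.all(diffs <= 1e-6)

    def test_permutation_equivariance(self, rng):
        DX = random_distance_matrix(rng, 7)
        DY = random_distance_matrix(rng, 7)
        mu = Marginal.uniform(7)
        cfg = SolverConfig(alpha=1.0, eps_gw=0.01, n_outer=6)
        res = solve_uagw(None, None, DX, DY, mu, mu, None, None, cfg)
        perm = rng.permutation(7)
        DXp = DistanceMatrix(DX.values[np.ix_(perm, perm)])
        resp = solve_uagw(None, None, DXp, DY, mu, mu, None, None, cfg)
        assert np.allclose(resp.P.plan, res.P.plan[perm], atol=1e-8)

    def test_rho_continuity_to_balanced(self, instance_10):
        X, Y, DX, DY = instance_10
        mu = Marginal.uniform(10)
        base = dict(alpha=1.0, eps_gw=0.02, n_outer=8, inner_max_iter=5000)
        bal = solve_uagw(None, None, DX, DY, mu, mu, None, None, SolverConfig(**base))
        unb = solve_uagw(
            None, None, DX, DY, mu, mu, None, None,
            SolverConfig(**base, rho_gw1=1e6, rho_gw2=1e6),
        )
        assert np.allclose(bal.P.plan, unb.P.plan, atol=1e-3)

    def test_unbalanced_destroys_orphan_mass(self):
        """Removing one cluster from Y: relaxed marginals let the orphaned
        X-cluster's rows shed mass below their uniform share."""
        sim = make_multiomic(n_cells=60, n_types=3, dx=8, dy=8, noise_sd=0.02, seed=7)
        labels = sim.X.labels
        keep_y = labels != "type0"
        X = sim.X.matrix
        Y = sim.Y.matrix[keep_y]
        DX = normalize_distances(knn_geodesic(X, 10))
        DY = normalize_distances(knn_geodesic(Y, 10))
        cfg = SolverConfig(
            alpha=1.0, eps_gw=1e-3, rho_gw1=0.01, rho_gw2=0.01, n_outer=20,
            inner_tol=1e-6,
        )
        res = solve_uagw(
            None, None, DX, DY, Marginal.uniform(len(X)), Marginal.uniform(int(keep_y.sum())),
            None, None, cfg,
        )
        orphan_mass = res.P.plan[labels == "type0"].sum()
        uniform_share = res.P.total_mass * np.mean(labels == "type0")
        assert orphan_mass < uniform_share

    def test_feature_self_recovery_coot(self, rng):
        """COOT on X = Y recovers the identity feature matching."""
        sim = make_multiomic(n_cells=60, n_types=3, dx=20, dy=20, noise_sd=0.0, seed=3)
        X = sim.X.matrix
        cfg = SolverConfig(alpha=0.0, eps_coot=1e-3, n_outer=20, inner_tol=1e-7)
        res = align("coot", X=X, Y=X, config=cfg)
        hits = np.mean(res.Q.plan.argmax(axis=1) == np.arange(20))
        assert hits == 1.0

    def test_sample_supervision_forces_diagonal(self, rng):
        X = rng.random((8, 4))
        Y = rng.random((8, 5))
        D = 1.0 - np.eye(8)
        cfg = SolverConfig(
            alpha=0.0, eps_coot=0.01, beta_sample=1e6, supervision_sample=D, n_outer=5,
        )
        res = align("coot", X=X, Y=Y, config=cfg)
        P = res.P.plan
        assert np.trace(P) / P.sum() >= 0.99


class TestAlignDispatch:
    def test_gw_dispatch_identity(self, instance_10):
        X, Y, DX, DY = instance_10
        mu = Marginal.uniform(10)
        cfg = SolverConfig(eps_gw=0.01, n_outer=5)
        via_align = align("gw", DX=DX, DY=DY, config=cfg)
        from dataclasses import replace

        direct = solve_uagw(
            None, None, DX, DY, mu, mu, None, None,
            replace(cfg, alpha=1.0, rho_gw1=INF, rho_gw2=INF),
        )
        assert np.array_equal(via_align.P.plan, direct.P.plan)

    def test_finite_rho_with_balanced_mode_errors(self, instance_10):
        X, Y, DX, DY = instance_10
        with pytest.raises(ValueError, match="balanced"):
            align("gw", DX=DX, DY=DY, config=SolverConfig(rho_gw1=0.1, rho_gw2=0.1))

    def test_agw_rejects_endpoint_alpha(self, instance_10):
        X, Y, DX, DY = instance_10
        with pytest.raises(ValueError, match="alpha"):
            align("agw", X=X, Y=Y, DX=DX, DY=DY, config=SolverConfig(alpha=1.0))

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            align("fgw")

    def test_density_diagnostic_decreases_with_entropy(self):
        """Entropic blurring: larger eps spreads each row's mass, so the
        fraction of sharp rows (density diagnostic) cannot grow with eps."""
        sim = make_multiomic(n_cells=40, n_types=2, dx=6, dy=6, noise_sd=0.0, seed=6)
        DX = normalize_distances(knn_geodesic(sim.X.matrix, 8))
        DY = normalize_distances(knn_geodesic(sim.Y.matrix, 8))
        densities = []
        for eps in (1e-3, 1e-2, 1e-1):
            res = align(
                "gw", DX=DX, DY=DY,
                config=SolverConfig(eps_gw=eps, n_outer=10, inner_tol=1e-6),
            )
            densities.append(coupling_density(res.P))
        assert densities[0] >= densities[1] >= densities[2]

    def test_agw_loss_trace_and_result_contract(self, instance_10):
        X, Y, DX, DY = instance_10
        cfg = SolverConfig(alpha=0.5, eps_gw=0.01, eps_coot=0.01, n_outer=8)
        res = align("agw", X=X, Y=Y, DX=DX, DY=DY, config=cfg)
        assert isinstance(res, AlignmentResult)
        assert res.Q is not None and res.Q.plan.shape == (6, 7)
        assert np.all(np.diff(res.loss_trace) <= 1e-6)
        assert 0.0 <= coupling_density(res.P) <= 1.0
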
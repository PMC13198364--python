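"""Unified block-coordinate-descent driver for (U)GW, (U)COOT, (U)AGW.

All six formulations are partial functions of one objective over three
couplings — two sample couplings ``P`` and ``P'`` (the Gromov-Wasserstein
pair) and a feature coupling ``Q`` (the co-optimal-transport block)::

    alpha     * [ <L(DX,DY), P (x) P'> + entropic + marginal-KL terms ]   (GW)
  + (1-alpha) * [ <L(X, Y ), P (x) Q > + entropic + marginal-KL terms ]   (COOT)
  + supervision terms

with squared loss ``L(a, b) = (a - b)^2``.  ``alpha = 1`` recovers (U)GW,
``alpha = 0`` recovers (U)COOT, hard marginal constraints (``rho = inf``)
recover the balanced variants.  Each BCD sweep holds two couplings fixed and
solves an exact entropic (un)balanced linear OT problem for the third
(:func:`otalign.ot_core.solve_local`); the fixed block's total mass rescales
``eps`` and ``rho`` and contributes a scalar cost offset, which makes every
block update an exact restricted minimization, so the traced objective is
non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import DistanceMatrix
from .ot_core import (
    INF,
    Coupling,
    DimensionError,
    DomainError,
    LocalProblem,
    Marginal,
    generalized_kl,
    solve_local,
)

__all__ = [
    "SolverConfig",
    "AlignmentResult",
    "SolverError",
    "local_cost_gw",
    "local_cost_coot",
    "solve_uagw",
    "align",
    "MODES",
    "coupling_density",
]

logger = logging.getLogger(__name__)

MODES = ("gw", "ugw", "coot", "ucoot", "agw", "uagw")


class SolverError(RuntimeError):
    """A block solve produced non-finite values; names the block and sweep."""


@dataclass
class SolverConfig:
    """Hyperparameters of the unified solver.

    Parameters
    ----------
    alpha : float in [0, 1]
        Trade-off between the GW term (geometry preservation, ``alpha -> 1``)
        and the COOT term (feature coupling, ``alpha -> 0``).
    eps_gw, eps_coot : float > 0
        Entropic regularization weights of the two terms.
    rho_gw1, rho_gw2 : float >= 0 or inf
        Sample-marginal KL relaxation of the GW term (inf = hard constraint).
    rho_coot1, rho_coot2 : float >= 0 or inf
        Joint sample/feature marginal relaxation of the COOT term per domain.
    beta_sample, beta_feature : float >= 0
        Supervision strengths; ``supervision_sample`` / ``supervision_feature``
        are matrices with 0 at pairs known to correspond, 1 elsewhere (any
        real-valued matrix is accepted).
    n_outer : int
        Maximum number of BCD sweeps.
    inner_max_iter, inner_tol : int, float
        Budget of each Sinkhorn block solve; ``inner_tol`` also serves as the
        stopping tolerance on the outer objective change.
    seed : int
        Recorded for provenance; the solver itself is deterministic.
    """

    alpha: float = 0.5
    eps_gw: float = 1e-3
    eps_coot: float = 1e-3
    rho_gw1: float = INF
    rho_gw2: float = INF
    rho_coot1: float = INF
    rho_coot2: float = INF
    beta_sample: float = 0.0
    beta_feature: float = 0.0
    supervision_sample: np.ndarray | None = None
    supervision_feature: np.ndarray | None = None
    n_outer: int = 50
    inner_max_iter: int = 1000
    inner_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise DomainError("alpha must lie in [0, 1]")
        if self.eps_gw <= 0 or self.eps_coot <= 0:
            raise DomainError("entropic weights must be > 0")
        for rho in (self.rho_gw1, self.rho_gw2, self.rho_coot1, self.rho_coot2):
            if not rho >= 0:
                raise DomainError("rho values must be >= 0 or inf")
        if self.n_outer < 1 or self.inner_max_iter < 1:
            raise DomainError("iteration budgets must be >= 1")


@dataclass
class AlignmentResult:
    """Fitted couplings, loss trace and convergence diagnostics."""

    P: Coupling
    P_prime: Coupling
    Q: Coupling | None
    loss_trace: np.ndarray
    converged: bool
    config_used: SolverConfig

    @property
    def P_symmetrized(self) -> Coupling:
        """Average of the two GW sample couplings, (P + P') / 2."""
        return Coupling(0.5 * (self.P.plan + self.P_prime.plan))


def local_cost_gw(DX: DistanceMatrix, DY: DistanceMatrix, other: Coupling) -> np.ndarray:
    """GW local cost against a fixed second sample coupling.

    ``C[i, k] = sum_{j,l} (DX[i,j] - DY[k,l])^2 * other[j,l]`` computed with
    the squared-loss factorization (never materializing the 4-index tensor)::

        C = DX^2 @ r 1^T + 1 c^T @ (DY^2)^T - 2 DX @ other @ DY^T

    with ``r``, ``c`` the row/column marginals of ``other``.
    """
    dx = DX.values if isinstance(DX, DistanceMatrix) else np.asarray(DX, float)
    dy = DY.values if isinstance(DY, DistanceMatrix) else np.asarray(DY, float)
    T = other.plan if isinstance(other, Coupling) else np.asarray(other, float)
    if T.shape != (dx.shape[0], dy.shape[0]):
        raise DimensionError(
            f"coupling shape {T.shape} does not match distance matrices "
            f"({dx.shape[0]}, {dy.shape[0]})"
        )
    r = T.sum(axis=1)
    c = T.sum(axis=0)
    return (
        (dx**2) @ r[:, None]
        + ((dy**2) @ c)[None, :]
        - 2.0 * dx @ T @ dy.T
    )


def local_cost_coot(X, Y, other: Coupling, axis: str) -> np.ndarray:
    """COOT local cost with the squared loss ``(X[i,j] - Y[k,l])^2``.

    ``axis='samples'``: ``other`` couples features (dx x dy) and the result
    couples samples; ``axis='features'``: the transposed analogue with a
    fixed sample coupling.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    T = other.plan if isinstance(other, Coupling) else np.asarray(other, float)
    if axis == "samples":
        if T.shape != (X.shape[1], Y.shape[1]):
            raise DimensionError(
                f"feature coupling shape {T.shape} does not match "
                f"({X.shape[1]}, {Y.shape[1]})"
            )
        r = T.sum(axis=1)
        c = T.sum(axis=0)
        return (X**2) @ r[:, None] + ((Y**2) @ c)[None, :] - 2.0 * X @ T @ Y.T
    if axis == "features":
        if T.shape != (X.shape[0], Y.shape[0]):
            raise DimensionError(
                f"sample coupling shape {T.shape} does not match "
                f"({X.shape[0]}, {Y.shape[0]})"
            )
        r = T.sum(axis=1)
        c = T.sum(axis=0)
        return (
            ((X**2).T @ r)[:, None]
            + ((Y**2).T @ c)[None, :]
            - 2.0 * X.T @ T @ Y
        )
    raise ValueError("axis must be 'samples' or 'features'")


def _kl_product_pair(a, b, u, v):
    """KL(a (x) b | u (x) v) for nonnegative measures via the mass identity.

    KL(a (x) b | u (x) v) = m(b) KL(a|u) + m(a) KL(b|v) + (m(a)-m(u))(m(b)-m(v)).
    """
    ma, mb = float(np.sum(a)), float(np.sum(b))
    mu, mv = float(np.sum(u)), float(np.sum(v))
    return (
        mb * generalized_kl(a, u)
        + ma * generalized_kl(b, v)
        + (ma - mu) * (mb - mv)
    )


def _fixed_block_offset(eps, rho1, rho2, T: Coupling, u: Marginal, v: Marginal):
    """Scalar cost offset induced by a fixed coupling block of mass m(T).

    From the product-KL decomposition, terms linear in the moving block's
    total mass: eps*(KL(T|u(x)v)+m(T)-m(u)m(v)) plus, per finite-rho side,
    rho_i*(KL(T#i|.)+m(T)-m(.)).
    """
    mT = T.total_mass
    off = eps * (
        generalized_kl(T.plan, np.outer(u.weights, v.weights))
        + mT
        - u.total_mass * v.total_mass
    )
    if np.isfinite(rho1):
        off += rho1 * (generalized_kl(T.marginal_1, u.weights) + mT - u.total_mass)
    if np.isfinite(rho2):
        off += rho2 * (generalized_kl(T.marginal_2, v.weights) + mT - v.total_mass)
    return off


def _scaled(value, mass):
    """rho * m(T), propagating the infinity sentinel."""
    return INF if np.isinf(value) else value * mass


def _term_objective(cost_lin, P, eps, rho1, rho2, other: Coupling, mu1, mu2, nu1, nu2):
    """One term (GW or COOT) of the global objective at the current blocks.

    ``cost_lin`` must be the linearized cost <L, . (x) other> evaluated
    against the *current* fixed block; entropic and marginal KLs use the
    product-measure decomposition over (P, other).
    """
    val = float(np.sum(cost_lin * P.plan))
    val += eps * _kl_product_pair(
        P.plan, other.plan, np.outer(mu1.weights, mu2.weights), np.outer(nu1.weights, nu2.weights)
    )
    if np.isfinite(rho1):
        val += rho1 * _kl_product_pair(
            P.marginal_1, other.marginal_1, mu1.weights, nu1.weights
        )
    if np.isfinite(rho2):
        val += rho2 * _kl_product_pair(
            P.marginal_2, other.marginal_2, mu2.weights, nu2.weights
        )
    return val


def _check_block(plan, block, sweep):
    if np.any(~np.isfinite(plan)):
        raise SolverError(f"non-finite values in block {block!r} at sweep {sweep}")


def solve_uagw(
    X,
    Y,
    DX: DistanceMatrix | None,
    DY: DistanceMatrix | None,
    mu_s1: Marginal,
    mu_s2: Marginal,
    mu_f1: Marginal | None,
    mu_f2: Marginal | None,
    config: SolverConfig,
) -> AlignmentResult:
    """Generic unbalanced augmented Gromov-Wasserstein block-coordinate descent.

    Initializes all couplings at product measures and alternates exact
    entropic local solves for ``P`` (blended GW + COOT cost), ``P'`` (pure GW,
    skipped at ``alpha = 0``) and ``Q`` (pure COOT on the feature axis,
    skipped at ``alpha = 1``).  Stops after ``config.n_outer`` sweeps or when
    the total objective changes by less than ``config.inner_tol``.

    ``X`` / ``Y`` may be None when ``alpha = 1`` (pure GW needs only the
    distance matrices); ``DX`` / ``DY`` may be None when ``alpha = 0``.
    """
    cfg = config
    a = cfg.alpha
    use_gw = a > 0.0
    use_coot = a < 1.0

    if use_gw and (DX is None or DY is None):
        raise DomainError("alpha > 0 requires distance matrices DX and DY")
    if use_coot and (X is None or Y is None):
        raise DomainError("alpha < 1 requires data matrices X and Y")
    if use_coot:
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if mu_f1 is None:
            mu_f1 = Marginal.uniform(X.shape[1])
        if mu_f2 is None:
            mu_f2 = Marginal.uniform(Y.shape[1])

    nx = mu_s1.n
    ny = mu_s2.n

    P = Coupling(np.outer(mu_s1.weights, mu_s2.weights))
    P_prime = Coupling(np.outer(mu_s1.weights, mu_s2.weights))
    Q = Coupling(np.outer(mu_f1.weights, mu_f2.weights)) if use_coot else None

    warm = {"P": None, "P_prime": None, "Q": None}
    loss_trace = []
    converged = False

    for sweep in range(1, cfg.n_outer + 1):
        # ---- update P (blended GW + COOT sample cost) -------------------
        cost = np.zeros((nx, ny))
        eps_eff = 0.0
        rho1_parts, rho2_parts = [], []
        if use_gw:
            mg = P_prime.total_mass
            cost += a * (
                local_cost_gw(DX, DY, P_prime)
                + _fixed_block_offset(cfg.eps_gw, cfg.rho_gw1, cfg.rho_gw2, P_prime, mu_s1, mu_s2)
            )
            eps_eff += a * cfg.eps_gw * mg
            rho1_parts.append(a * _scaled(cfg.rho_gw1, mg))
            rho2_parts.append(a * _scaled(cfg.rho_gw2, mg))
        if use_coot:
            mq = Q.total_mass
            cost += (1.0 - a) * (
                local_cost_coot(X, Y, Q, axis="samples")
                + _fixed_block_offset(cfg.eps_coot, cfg.rho_coot1, cfg.rho_coot2, Q, mu_f1, mu_f2)
            )
            eps_eff += (1.0 - a) * cfg.eps_coot * mq
            rho1_parts.append((1.0 - a) * _scaled(cfg.rho_coot1, mq))
            rho2_parts.append((1.0 - a) * _scaled(cfg.rho_coot2, mq))
        rho1_eff = sum(rho1_parts)  # inf propagates: any hard side dominates
        rho2_eff = sum(rho2_parts)
        prob = LocalProblem(
            cost=cost,
            mu1=mu_s1,
            mu2=mu_s2,
            epsilon=eps_eff,
            rho1=rho1_eff,
            rho2=rho2_eff,
            supervision=cfg.supervision_sample,
            beta=cfg.beta_sample,
        )
        sol = solve_local(
            prob, max_iter=cfg.inner_max_iter, tol=cfg.inner_tol, warm_start=warm["P"]
        )
        _check_block(sol.coupling.plan, "P", sweep)
        P = sol.coupling
        warm["P"] = (sol.f, sol.g)

        # ---- update P' (pure GW block, alpha factors out) ---------------
        if use_gw:
            mp = P.total_mass
            cost_pp = local_cost_gw(DX, DY, P) + _fixed_block_offset(
                cfg.eps_gw, cfg.rho_gw1, cfg.rho_gw2, P, mu_s1, mu_s2
            )
            prob = LocalProblem(
                cost=cost_pp,
                mu1=mu_s1,
                mu2=mu_s2,
                epsilon=cfg.eps_gw * mp,
                rho1=_scaled(cfg.rho_gw1, mp),
                rho2=_scaled(cfg.rho_gw2, mp),
            )
            sol = solve_local(
                prob, max_iter=cfg.inner_max_iter, tol=cfg.inner_tol, warm_start=warm["P_prime"]
            )
            _check_block(sol.coupling.plan, "P_prime", sweep)
            P_prime = sol.coupling
            warm["P_prime"] = (sol.f, sol.g)

        # ---- update Q (pure COOT feature block) -------------------------
        if use_coot:
            mp = P.total_mass
            cost_q = local_cost_coot(X, Y, P, axis="features") + _fixed_block_offset(
                cfg.eps_coot, cfg.rho_coot1, cfg.rho_coot2, P, mu_s1, mu_s2
            )
            prob = LocalProblem(
                cost=cost_q,
                mu1=mu_f1,
                mu2=mu_f2,
                epsilon=cfg.eps_coot * mp,
                rho1=_scaled(cfg.rho_coot1, mp),
                rho2=_scaled(cfg.rho_coot2, mp),
                supervision=cfg.supervision_feature,
                beta=cfg.beta_feature,
            )
            sol = solve_local(
                prob, max_iter=cfg.inner_max_iter, tol=cfg.inner_tol, warm_start=warm["Q"]
            )
            _check_block(sol.coupling.plan, "Q", sweep)
            Q = sol.coupling
            warm["Q"] = (sol.f, sol.g)

        # ---- total objective -------------------------------------------
        obj = 0.0
        if use_gw:
            obj += a * _term_objective(
                local_cost_gw(DX, DY, P_prime),
                P,
                cfg.eps_gw,
                cfg.rho_gw1,
                cfg.rho_gw2,
                P_prime,
                mu_s1,
                mu_s2,
                mu_s1,
                mu_s2,
            )
        if use_coot:
            obj += (1.0 - a) * _term_objective(
                local_cost_coot(X, Y, Q, axis="samples"),
                P,
                cfg.eps_coot,
                cfg.rho_coot1,
                cfg.rho_coot2,
                Q,
                mu_s1,
                mu_s2,
                mu_f1,
                mu_f2,
            )
            if cfg.supervision_feature is not None and cfg.beta_feature > 0:
                obj += (1.0 - a) * cfg.beta_feature * float(
                    np.sum(cfg.supervision_feature * Q.plan)
                )
        if cfg.supervision_sample is not None and cfg.beta_sample > 0:
            obj += cfg.beta_sample * float(np.sum(cfg.supervision_sample * P.plan))
        loss_trace.append(obj)
        logger.debug("sweep %d: objective %.10g (mass P=%.6g)", sweep, obj, P.total_mass)

        if sweep > 1 and abs(loss_trace[-2] - loss_trace[-1]) < cfg.inner_tol:
            converged = True
            break

    if not converged:
        logger.warning(
            "BCD did not reach objective tolerance %.1e in %d sweeps",
            cfg.inner_tol,
            cfg.n_outer,
        )
    return AlignmentResult(
        P=P,
        P_prime=P_prime,
        Q=Q,
        loss_trace=np.asarray(loss_trace),
        converged=converged,
        config_used=cfg,
    )


_DEFAULT_FINITE_RHO = 0.1  # middle of the usual {0.01, 0.1, 1} search grid


def align(
    mode: str,
    X=None,
    Y=None,
    DX: DistanceMatrix | None = None,
    DY: DistanceMatrix | None = None,
    mu_s1: Marginal | None = None,
    mu_s2: Marginal | None = None,
    mu_f1: Marginal | None = None,
    mu_f2: Marginal | None = None,
    config: SolverConfig | None = None,
) -> AlignmentResult:
    """Convenience dispatch fixing ``alpha`` and the ``rho`` sentinels per mode.

    ============  =========  =======================================
    mode          alpha      marginal constraints
    ============  =========  =======================================
    ``gw``        1          hard (rho_gw = inf)
    ``ugw``       1          relaxed (finite rho_gw)
    ``coot``      0          hard (rho_coot = inf)
    ``ucoot``     0          relaxed (finite rho_coot)
    ``agw``       config's   hard everywhere
    ``uagw``      config's   as configured
    ============  =========  =======================================

    Supplying a finite rho together with a balanced mode is a parameter
    error (explicit, never silently overridden).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    cfg = config if config is not None else SolverConfig()

    def _require_balanced(names):
        for name in names:
            if np.isfinite(getattr(cfg, name)):
                raise ValueError(
                    f"mode {mode!r} is balanced but config.{name} is finite; "
                    "use the unbalanced mode instead"
                )

    if mode == "gw":
        _require_balanced(["rho_gw1", "rho_gw2"])
        cfg = replace(cfg, alpha=1.0, rho_gw1=INF, rho_gw2=INF)
    elif mode == "ugw":
        if np.isinf(cfg.rho_gw1) and np.isinf(cfg.rho_gw2):
            logger.info("ugw with infinite rho_gw: using default rho=%.3g", _DEFAULT_FINITE_RHO)
            cfg = replace(cfg, rho_gw1=_DEFAULT_FINITE_RHO, rho_gw2=_DEFAULT_FINITE_RHO)
        cfg = replace(cfg, alpha=1.0)
    elif mode == "coot":
        _require_balanced(["rho_coot1", "rho_coot2"])
        cfg = replace(cfg, alpha=0.0, rho_coot1=INF, rho_coot2=INF)
    elif mode == "ucoot":
        if np.isinf(cfg.rho_coot1) and np.isinf(cfg.rho_coot2):
            logger.info("ucoot with infinite rho_coot: using default rho=%.3g", _DEFAULT_FINITE_RHO)
            cfg = replace(cfg, rho_coot1=_DEFAULT_FINITE_RHO, rho_coot2=_DEFAULT_FINITE_RHO)
        cfg = replace(cfg, alpha=0.0)
    elif mode == "agw":
        _require_balanced(["rho_gw1", "rho_gw2", "rho_coot1", "rho_coot2"])
        if cfg.alpha in (0.0, 1.0):
            raise ValueError("agw requires 0 < alpha < 1; use gw/coot for the endpoints")
    # uagw: as configured

    if mu_s1 is None:
        n1 = DX.n if (DX is not None and cfg.alpha > 0) else np.asarray(X).shape[0]
        mu_s1 = Marginal.uniform(n1)
    if mu_s2 is None:
        n2 = DY.n if (DY is not None and cfg.alpha > 0) else np.asarray(Y).shape[0]
        mu_s2 = Marginal.uniform(n2)
    return solve_uagw(X, Y, DX, DY, mu_s1, mu_s2, mu_f1, mu_f2, cfg)


def coupling_density(plan) -> float:
    """Fraction of rows whose largest entry holds more than half the row mass.

    A qualitative sharpness diagnostic used when grid-searching eps: values
    near 1 indicate near-deterministic (sparse) rows, values near 0 an
    over-smoothed coupling.  Zero-mass rows are skipped.
    """
    P = plan.plan if isinstance(plan, Coupling) else np.asarray(plan, float)
    rows = P.sum(axis=1)
    keep = rows > 0
    if not np.any(keep):
        return 0.0
    frac = P[keep].max(axis=1) / rows[keep]
    return float(np.mean(frac > 0.5))
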
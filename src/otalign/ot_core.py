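"""Entropic, optionally unbalanced, optionally supervised linear optimal transport.

Every alignment formulation in this package (GW, COOT and their augmented /
unbalanced variants) reduces, one block-coordinate-descent step at a time, to a
single *local* problem over a coupling matrix ``P``::

    min_P  <C + beta * D, P>
           + eps  * KL(P    | mu1 (x) mu2)
           + rho1 * KL(P#1  | mu1)
           + rho2 * KL(P#2  | mu2)

where ``P#1`` / ``P#2`` are the row / column sums (pushforward marginals) of
``P``, ``KL`` is the generalized Kullback-Leibler divergence between
nonnegative measures, ``D`` is an optional supervision matrix (0 for pairs
known to correspond, 1 otherwise, by convention) and ``rho = inf`` encodes a
hard marginal constraint (classic balanced Sinkhorn).

The solver runs Sinkhorn-type dual updates entirely in the log domain, with
the standard unbalanced damping factor ``rho / (rho + eps)`` applied to each
dual step, so it is stable for ``eps`` as small as 1e-4 on costs scaled to
``[0, 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DimensionError",
    "DomainError",
    "Marginal",
    "Coupling",
    "LocalProblem",
    "LocalSolution",
    "generalized_kl",
    "solve_local",
    "local_objective",
]

logger = logging.getLogger(__name__)

INF = float("inf")


class DimensionError(ValueError):
    """Shapes of interacting arrays do not match."""


class DomainError(ValueError):
    """A numeric argument lies outside its mathematical domain."""


def generalized_kl(p, r) -> float:
    """Generalized KL divergence between nonnegative measures.

    ``KL(p | r) = sum p * log(p / r) - sum p + sum r`` with the convention
    ``0 * log 0 = 0``.  Unlike the probability-simplex KL this is finite and
    meaningful for measures of unequal total mass, and is zero iff ``p == r``
    entrywise.

    Parameters
    ----------
    p : array_like
        Nonnegative vector or matrix.
    r : array_like
        Reference measure, strictly positive wherever ``p > 0``.

    Returns
    -------
    float
        Nonnegative divergence value.
    """
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if p.shape != r.shape:
        raise DimensionError(f"shape mismatch: p {p.shape} vs r {r.shape}")
    if np.any(p < 0):
        raise DomainError("p must be nonnegative")
    mask = p > 0
    if np.any(r[mask] <= 0):
        raise DomainError("r must be strictly positive wherever p > 0")
    pm = p[mask]
    return float(np.sum(pm * np.log(pm / r[mask])) - p.sum() + r.sum())


@dataclass(frozen=True)
class Marginal:
    """A strictly positive mass vector over the atoms of one domain."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise DimensionError("marginal must be a nonempty 1-D vector")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise DomainError("marginal entries must be finite and > 0")
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, n: int, total_mass: float = 1.0) -> "Marginal":
        return cls(np.full(n, total_mass / n))

    @property
    def n(self) -> int:
        return self.weights.size

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())


@dataclass
class Coupling:
    """A nonnegative transport plan together with its pushforward marginals."""

    plan: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.plan, dtype=float)
        if p.ndim != 2:
            raise DimensionError("coupling plan must be a 2-D matrix")
        if not np.all(np.isfinite(p)):
            raise DomainError("coupling plan must be finite")
        if np.any(p < 0):
            raise DomainError("coupling plan must be nonnegative")
        self.plan = p

    @property
    def marginal_1(self) -> np.ndarray:
        """Row sums: the pushforward onto the first domain (P#1)."""
        return self.plan.sum(axis=1)

    @property
    def marginal_2(self) -> np.ndarray:
        """Column sums: the pushforward onto the second domain (P#2)."""
        return self.plan.sum(axis=0)

    @property
    def total_mass(self) -> float:
        return float(self.plan.sum())

    @property
    def shape(self):
        return self.plan.shape


@dataclass
class LocalProblem:
    """One entropic (un)balanced linear OT instance.

    ``rho1`` / ``rho2`` of ``inf`` mean hard marginal constraints on that
    side; finite values are KL relaxation weights; ``0`` removes the marginal
    term entirely (closed-form solution ``(mu1 (x) mu2) * exp(-C/eps)``).
    """

    cost: np.ndarray
    mu1: Marginal
    mu2: Marginal
    epsilon: float
    rho1: float = INF
    rho2: float = INF
    supervision: np.ndarray | None = None
    beta: float = 0.0

    def __post_init__(self):
        self.cost = np.asarray(self.cost, dtype=float)
        if self.cost.ndim != 2:
            raise DimensionError("cost must be a 2-D matrix")
        if not np.all(np.isfinite(self.cost)):
            raise DomainError("cost matrix must be finite")
        if self.cost.shape != (self.mu1.n, self.mu2.n):
            raise DimensionError(
                f"cost shape {self.cost.shape} does not match marginals "
                f"({self.mu1.n}, {self.mu2.n})"
            )
        if not (self.epsilon > 0):
            raise DomainError("epsilon must be > 0")
        for rho in (self.rho1, self.rho2):
            if not (rho >= 0):  # inf passes
                raise DomainError("rho must be >= 0 or inf")
        if self.beta < 0:
            raise DomainError("beta must be >= 0")
        if self.supervision is not None:
            self.supervision = np.asarray(self.supervision, dtype=float)
            if self.supervision.shape != self.cost.shape:
                raise DimensionError("supervision matrix shape must equal cost shape")
            if not np.all(np.isfinite(self.supervision)):
                raise DomainError("supervision matrix must be finite")

    @property
    def effective_cost(self) -> np.ndarray:
        """Cost with the supervision term beta * D folded in."""
        if self.supervision is None or self.beta == 0.0:
            return self.cost
        return self.cost + self.beta * self.supervision


@dataclass
class LocalSolution:
    """Output of :func:`solve_local`: the coupling plus diagnostics."""

    coupling: Coupling
    converged: bool
    n_iter: int
    f: np.ndarray = field(repr=False, default=None)
    g: np.ndarray = field(repr=False, default=None)
    objective_trace: np.ndarray | None = field(repr=False, default=None)


def _plan_from_duals(f, g, log_mu1, log_mu2, cost, eps):
    logP = (
        log_mu1[:, None]
        + log_mu2[None, :]
        + (f[:, None] + g[None, :] - cost) / eps
    )
    return np.exp(logP)


def _lse_rows(A):
    mx = A.max(axis=1)
    return mx + np.log(np.exp(A - mx[:, None]).sum(axis=1))


def _lse_cols(A):
    mx = A.max(axis=0)
    return mx + np.log(np.exp(A - mx[None, :]).sum(axis=0))


def _sinkhorn_loop(
    C, eps, rho1, rho2, lmu1, lmu2, mu1, mu2, f, g, max_iter, tol,
    problem=None, trace=None, check_every=5,
):
    """Damped log-domain Sinkhorn iterations at a fixed eps.

    Returns (f, g, iterations used, converged).  Convergence (tested every
    ``check_every`` iterations): hard-constraint sides need total-variation
    marginal violation < tol, relaxed sides need sup-norm dual change < tol.
    """
    bal1 = np.isinf(rho1)
    bal2 = np.isinf(rho2)
    tau1 = 1.0 if bal1 else rho1 / (rho1 + eps)
    tau2 = 1.0 if bal2 else rho2 / (rho2 + eps)
    M = -C / eps
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f_prev, g_prev = f, g
        # f_i = -tau1 * eps * LSE_j( log mu2_j + (g_j - C_ij)/eps )
        A = M + (g / eps + lmu2)[None, :]
        f = -tau1 * eps * _lse_rows(A)
        A = M + (f / eps + lmu1)[:, None]
        g = -tau2 * eps * _lse_cols(A)

        check = trace is not None or it % check_every == 0 or it == max_iter
        if not check:
            continue

        err_dual = 0.0
        if not bal1:
            err_dual = max(err_dual, float(np.max(np.abs(f - f_prev))))
        if not bal2:
            err_dual = max(err_dual, float(np.max(np.abs(g - g_prev))))

        err_marg = 0.0
        if bal1 or bal2 or trace is not None:
            # A already holds M + (f/eps + lmu1); adding the g part gives log P
            P = np.exp(A + (g / eps + lmu2)[None, :])
            if bal1:
                err_marg = max(err_marg, float(np.abs(P.sum(axis=1) - mu1).sum()))
            if bal2:
                err_marg = max(err_marg, float(np.abs(P.sum(axis=0) - mu2).sum()))
            if trace is not None:
                trace.append(local_objective(problem, P))

        if max(err_dual, err_marg) < tol:
            converged = True
            break
    return f, g, it, converged


def solve_local(
    problem: LocalProblem,
    max_iter: int = 1000,
    tol: float = 1e-9,
    warm_start: tuple[np.ndarray, np.ndarray] | None = None,
    track_objective: bool = False,
    eps_scaling: bool = True,
) -> LocalSolution:
    """Solve one entropic (un)balanced OT problem by log-domain Sinkhorn.

    Dual updates are damped by ``rho / (rho + eps)`` per side (factor 1 for a
    hard constraint).  Convergence: sides with a hard constraint must have
    total-variation marginal violation below ``tol``; relaxed sides must have
    sup-norm dual change below ``tol``.  Non-convergence sets
    ``converged=False`` and logs a warning — never silent.

    Parameters
    ----------
    problem : LocalProblem
    max_iter : int
        Iteration budget of the final stage (>= 1).
    tol : float
        Convergence tolerance (see above).
    warm_start : (f, g), optional
        Initial dual potentials, e.g. from the previous BCD sweep.
    track_objective : bool
        If True, record the primal objective after every final-stage
        iteration in ``objective_trace`` (adds one O(nm) pass per iteration).
    eps_scaling : bool
        Cold starts anneal eps from a fraction of the cost range down to the
        target in factor-5 stages, warm-starting the duals at each stage —
        this is what makes small-eps solves affordable.  Ignored when a
        ``warm_start`` is supplied (the duals are already near-optimal).
    """
    if max_iter < 1:
        raise DomainError("max_iter must be >= 1")
    C = problem.effective_cost
    eps = problem.epsilon
    mu1 = problem.mu1.weights
    mu2 = problem.mu2.weights
    lmu1 = np.log(mu1)
    lmu2 = np.log(mu2)
    n, m = C.shape

    if warm_start is not None:
        f = np.array(warm_start[0], dtype=float, copy=True)
        g = np.array(warm_start[1], dtype=float, copy=True)
    else:
        f = np.zeros(n)
        g = np.zeros(m)
        span = float(C.max() - C.min()) if C.size else 0.0
        if eps_scaling and span > 0 and eps < 0.05 * span:
            e = 0.05 * span
            while e > 5.0 * eps:
                f, g, _, _ = _sinkhorn_loop(
                    C, e, problem.rho1, problem.rho2, lmu1, lmu2, mu1, mu2,
                    f, g, max_iter=100, tol=max(tol, 1e-3 * e),
                )
                e /= 5.0

    trace = [] if track_objective else None
    f, g, it, converged = _sinkhorn_loop(
        C, eps, problem.rho1, problem.rho2, lmu1, lmu2, mu1, mu2,
        f, g, max_iter, tol, problem=problem, trace=trace,
    )

    P = _plan_from_duals(f, g, lmu1, lmu2, C, eps)
    if not np.all(np.isfinite(P)):
        raise DomainError("local solve produced non-finite plan entries")
    if not converged:
        logger.warning(
            "solve_local did not converge in %d iterations (tol=%.1e)", max_iter, tol
        )
    return LocalSolution(
        coupling=Coupling(P),
        converged=converged,
        n_iter=it,
        f=f,
        g=g,
        objective_trace=np.asarray(trace) if track_objective else None,
    )


def local_objective(problem: LocalProblem, plan) -> float:
    """Evaluate the local objective at a given plan.

    Hard-constraint sides (``rho = inf``) contribute no penalty term: the
    constraint is understood as enforced by the solver, so the returned value
    is the objective of the constrained problem.
    """
    P = plan.plan if isinstance(plan, Coupling) else np.asarray(plan, dtype=float)
    C = problem.effective_cost
    mu1 = problem.mu1.weights
    mu2 = problem.mu2.weights
    val = float(np.sum(C * P))
    val += problem.epsilon * generalized_kl(P, np.outer(mu1, mu2))
    if np.isfinite(problem.rho1) and problem.rho1 > 0:
        val += problem.rho1 * generalized_kl(P.sum(axis=1), mu1)
    if np.isfinite(problem.rho2) and problem.rho2 > 0:
        val += problem.rho2 * generalized_kl(P.sum(axis=0), mu2)
    return val
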
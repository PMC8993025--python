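"""Marginal-maximum-likelihood calibration via Bock-Aitkin EM.

The latent ability density is fixed at N(0, 1) (location and scale are
imposed for identifiability).  The E-step places each person on a fixed
quadrature grid; the M-step maximizes the expected complete-data
log-likelihood item by item in an unconstrained parameterization
``(log lambda, tau_2, log increments)`` that preserves positivity and
threshold ordering.  Calibration-time person estimates are EAP under the
standard-normal latent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp, ndtri
from scipy.stats import norm

from .grm import (
    MISSING,
    PROB_FLOOR,
    AbilityEstimate,
    ItemBank,
    ItemParameters,
    ResponseMatrix,
)

__all__ = [
    "QuadratureGrid",
    "MMLConfig",
    "MMLCalibrationResult",
    "standard_normal_grid",
    "calibrate_mml",
    "eap_under_standard_normal",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature nodes with normalized non-negative weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise ValueError("nodes and weights must be matching 1-D arrays")
        if (np.diff(nodes) <= 0).any():
            raise ValueError("nodes must be strictly increasing")
        if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")


def standard_normal_grid(n: int = 61, bound: float = 6.0) -> QuadratureGrid:
    """Equally spaced nodes on [-bound, bound] with renormalized N(0,1) weights."""
    nodes = np.linspace(-bound, bound, n)
    w = norm.pdf(nodes)
    return QuadratureGrid(nodes=nodes, weights=w / w.sum())


@dataclass(frozen=True)
class MMLConfig:
    """EM tolerances and quadrature settings."""

    tol: float = 1e-5
    max_iter: int = 500
    n_quadrature: int = 61
    quadrature_bound: float = 6.0
    inner_maxiter: int = 30

    def grid(self) -> QuadratureGrid:
        return standard_normal_grid(self.n_quadrature, self.quadrature_bound)


@dataclass(frozen=True)
class MMLCalibrationResult:
    bank: ItemBank
    person_estimates: tuple[AbilityEstimate, ...]
    loglik_trace: np.ndarray
    converged: bool
    n_iterations: int


def _infer_categories(responses: ResponseMatrix) -> np.ndarray:
    """Per-item category counts from data; every code 1..J must be observed."""
    X = responses.responses
    ncat = np.zeros(responses.n_items, dtype=int)
    for i, item_id in enumerate(responses.item_ids):
        col = X[:, i]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(f"item {item_id!r} has no observed responses")
        J = int(obs.max())
        if J < 2:
            raise ValueError(f"item {item_id!r} shows a single category; cannot calibrate")
        seen = np.bincount(obs, minlength=J + 1)[1:]
        if (seen == 0).any():
            j = int(np.argmin(seen > 0)) + 1
            raise ValueError(
                f"item {item_id!r}: category {j} is never observed; "
                "collapse categories before calibrating"
            )
        ncat[i] = J
    return ncat


def _initial_item(col: np.ndarray, J: int) -> np.ndarray:
    """Start values: lambda = 1, thresholds at normal quantiles of the
    observed cumulative frequencies (gap-regularized)."""
    obs = col[col != MISSING]
    counts = np.bincount(obs, minlength=J + 1)[1:].astype(float)
    p_ge = 1.0 - np.cumsum(counts)[: J - 1] / counts.sum()  # Pr(X >= j+1)
    tau = ndtri(np.clip(1.0 - p_ge, 1e-4, 1 - 1e-4))
    for k in range(1, tau.size):  # enforce strict ordering at start
        tau[k] = max(tau[k], tau[k - 1] + 0.05)
    return np.concatenate(([0.0], _tau_to_free(tau)))  # log lambda = 0


def _tau_to_free(tau: np.ndarray) -> np.ndarray:
    return np.concatenate(([tau[0]], np.log(np.diff(tau)))) if tau.size > 1 else tau


def _free_to_tau(free: np.ndarray) -> np.ndarray:
    if free.size == 1:
        return free.copy()
    return free[0] + np.concatenate(([0.0], np.cumsum(np.exp(free[1:]))))


def _item_objective(params: np.ndarray, nodes: np.ndarray, r: np.ndarray):
    """Negative expected complete-data log-likelihood for one item + gradient.

    ``r`` is the (Q, J) table of expected response counts per node/category.
    """
    lam = np.exp(params[0])
    tau = _free_to_tau(params[1:])
    Q, J = r.shape
    tau_pad = np.concatenate(([-np.inf], tau, [np.inf]))
    F = expit(lam * (nodes[:, None] - tau_pad))
    F[:, 0], F[:, -1] = 1.0, 0.0
    u = F * (1.0 - F)  # 0 at virtual boundaries
    P = np.maximum(F[:, :-1] - F[:, 1:], PROB_FLOOR)
    f = float((r * np.log(P)).sum())

    w = r / P  # (Q, J)
    # d f / d tau_k: tau_k is the upper cut of category k, lower cut of k+1
    g_tau = lam * (u[:, 1:-1] * (w[:, :-1] - w[:, 1:])).sum(axis=0)
    # d f / d lambda, via (theta - tau) u terms with boundaries zeroed
    z = np.zeros_like(u)
    z[:, 1:-1] = (nodes[:, None] - tau) * u[:, 1:-1]
    g_lam = ((z[:, :-1] - z[:, 1:]) * w).sum()
    grad = np.empty_like(params)
    grad[0] = g_lam * lam  # chain rule through log lambda
    if tau.size == 1:
        grad[1] = g_tau[0]
    else:
        tail = np.cumsum(g_tau[::-1])[::-1]  # sum_{m >= k} df/dtau_m
        grad[1] = tail[0]
        grad[2:] = tail[1:] * np.exp(params[2:])
    return -f, -grad


def _person_grid_loglik(
    X: np.ndarray, lam: np.ndarray, tau_pad: np.ndarray, nodes: np.ndarray
) -> np.ndarray:
    """(P, Q) log-likelihood of each person at each quadrature node."""
    P, I = X.shape
    Q = nodes.size
    L = np.zeros((P, Q))
    for i in range(I):
        col = X[:, i]
        obs = col != MISSING
        if not obs.any():
            continue
        F = expit(lam[i] * (nodes[None, :] - tau_pad[i][:, None]))
        F[0], F[-1] = 1.0, 0.0
        logp = np.log(np.maximum(F[:-1] - F[1:], PROB_FLOOR))  # (J, Q)
        L[obs] += logp[col[obs] - 1]
    return L


def calibrate_mml(
    responses: ResponseMatrix,
    config: MMLConfig | None = None,
) -> MMLCalibrationResult:
    """Calibrate an item bank by marginal maximum likelihood EM.

    Convergence is declared when the marginal log-likelihood improves by
    less than ``config.tol`` between iterations; otherwise the result is
    returned flagged as non-converged after ``config.max_iter`` iterations.
    """
    config = config or MMLConfig()
    if responses.n_items < 2:
        raise ValueError("calibration requires at least 2 items")
    ncat = _infer_categories(responses)
    X = responses.responses
    P, I = X.shape
    grid = config.grid()
    nodes, wq = grid.nodes, grid.weights
    jmax = int(ncat.max())

    params = [_initial_item(X[:, i], ncat[i]) for i in range(I)]

    def padded(params_list):
        lam = np.array([np.exp(p[0]) for p in params_list])
        tau_pad = np.full((I, jmax + 1), np.inf)
        tau_pad[:, 0] = -np.inf
        for i, p in enumerate(params_list):
            tau_pad[i, 1 : ncat[i]] = _free_to_tau(p[1:])
        return lam, tau_pad

    trace: list[float] = []
    converged = False
    it = 0
    log_wq = np.log(wq)
    for it in range(1, config.max_iter + 1):
        lam, tau_pad = padded(params)
        # E-step: posterior weights of each person over the grid
        L = _person_grid_loglik(X, lam, tau_pad, nodes)
        joint = L + log_wq[None, :]
        marg = logsumexp(joint, axis=1)
        trace.append(float(marg.sum()))
        W = np.exp(joint - marg[:, None])  # rows sum to 1 exactly up to fp
        # M-step: one bounded quasi-Newton ascent per item
        for i in range(I):
            col = X[:, i]
            obs = col != MISSING
            if not obs.any():
                continue
            r = np.zeros((nodes.size, ncat[i]))
            np.add.at(r.T, col[obs] - 1, W[obs])
            res = minimize(
                _item_objective,
                params[i],
                args=(nodes, r),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": config.inner_maxiter},
            )
            if np.isfinite(res.fun):
                params[i] = res.x
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break

    lam, tau_pad = padded(params)
    items = tuple(
        ItemParameters(
            item_id=responses.item_ids[i],
            n_categories=int(ncat[i]),
            discrimination=float(lam[i]),
            thresholds=tuple(tau_pad[i, 1 : ncat[i]]),
        )
        for i in range(I)
    )
    bank = ItemBank(domain="mml", items=items)
    estimates = tuple(
        eap_under_standard_normal(X[p], bank, grid) for p in range(P)
    )
    if not converged:
        warnings.warn(
            f"MML EM did not converge in {it} iterations "
            f"(last change {abs(trace[-1] - trace[-2]) if len(trace) > 1 else np.nan:.3g})"
        )
    return MMLCalibrationResult(
        bank=bank,
        person_estimates=estimates,
        loglik_trace=np.array(trace),
        converged=converged,
        n_iterations=it,
    )


def eap_under_standard_normal(
    responses_row: np.ndarray,
    bank: ItemBank,
    grid: QuadratureGrid | None = None,
) -> AbilityEstimate:
    """EAP ability under the fixed N(0,1) latent, by grid quadrature.

    These are the calibration-time person scores implied by MML.
    """
    grid = grid or standard_normal_grid()
    x = np.asarray(responses_row, dtype=np.int64)
    if (x == MISSING).all():
        raise ValueError("person has no observed responses; cannot be scored")
    lam, tau, ncat = bank.arrays()
    tau_rows = [np.concatenate(([-np.inf], it.thresholds, [np.inf])) for it in bank.items]
    L = np.zeros(grid.nodes.size)
    for i, row in enumerate(tau_rows):
        if x[i] == MISSING:
            continue
        F = expit(lam[i] * (grid.nodes[None, :] - row[:, None]))
        F[0], F[-1] = 1.0, 0.0
        L += np.log(np.maximum(F[x[i] - 1] - F[x[i]], PROB_FLOOR))
    logw = L + np.log(grid.weights)
    w = np.exp(logw - logsumexp(logw))
    mean = float(w @ grid.nodes)
    var = float(w @ (grid.nodes - mean) ** 2)
    return AbilityEstimate(theta=mean, se=float(np.sqrt(max(var, 0.0))), method="CALIBRATION")
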
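"""Ability scoring against a fixed, calibrated item bank.

Four estimators, each returning ``(theta_hat, se)``:

``score_mle``
    Maximum likelihood; SE from inverse Fisher information.  Diverges to
    the optimizer bound (flagged) on all-extreme response patterns.
``score_wle``
    Jeffreys-weighted likelihood — maximizes ``l(theta) + 0.5 * log
    I(theta)``, which for dichotomous items is exactly Warm's bias-corrected
    estimator and stays finite on extreme patterns.
``score_eap_truncated``
    Posterior mean/SD under a normal prior truncated to a compact interval
    ``[-B, B]``, computed by quadrature.
``score_mml``
    Fixed point of marginal-likelihood maximization: the Gaussian ability
    approximation's variance is recomputed from the Fisher information at
    each iterate.

Item-parameter uncertainty is ignored throughout (point estimates only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .grm import (
    MISSING,
    AbilityEstimate,
    ItemBank,
    ResponseMatrix,
    fisher_information,
    log_likelihood,
    logistic_normal_cdf,
)

__all__ = [
    "ScoringConfig",
    "ScoreTable",
    "score_mle",
    "score_wle",
    "score_eap_truncated",
    "score_mml",
    "score_all",
]


@dataclass(frozen=True)
class ScoringConfig:
    truncation_bound: float = 5.0
    prior_sd: float = 1.0
    quadrature_points: int = 141
    optimizer_bounds: tuple[float, float] = (-6.0, 6.0)
    fixed_point_tol: float = 1e-4
    max_fixed_point_iters: int = 50

    def __post_init__(self) -> None:
        if self.truncation_bound <= 0:
            raise ValueError("truncation_bound must be > 0")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be > 0")
        if self.quadrature_points < 21:
            raise ValueError("quadrature_points must be >= 21")
        lo, hi = self.optimizer_bounds
        if lo >= hi:
            raise ValueError("invalid optimizer_bounds")


@dataclass(frozen=True)
class ScoreTable:
    """Batch scoring output; unscorable persons are dropped (counted)."""

    person_ids: tuple[str, ...]
    estimates: tuple[AbilityEstimate, ...]
    method: str
    n_flagged: int
    n_unscorable: int


def _check_responses(responses_row, bank: ItemBank) -> np.ndarray:
    x = np.asarray(responses_row, dtype=np.int64)
    if (x == MISSING).all():
        raise ValueError("person has no observed responses; cannot be scored")
    return x


def _maximize(objective, bounds: tuple[float, float]) -> float:
    """Maximize a scalar objective with restarts at {-2, 0, 2}.

    Ties within 1e-9 are broken toward the candidate nearest zero.
    """
    lo, hi = bounds
    starts = [s for s in (-2.0, 0.0, 2.0) if lo <= s <= hi] or [0.5 * (lo + hi)]
    candidates = []
    for s in starts:
        res = minimize(
            lambda th: -objective(th[0]),
            x0=[s],
            bounds=[bounds],
            method="L-BFGS-B",
        )
        candidates.append((float(res.fun), float(res.x[0])))
    best = min(f for f, _ in candidates)
    tied = [th for f, th in candidates if f <= best + 1e-9]
    return min(tied, key=abs)


def score_mle(responses_row, bank: ItemBank, config: ScoringConfig | None = None) -> AbilityEstimate:
    """Maximum-likelihood score; flagged when pinned at an optimizer bound."""
    config = config or ScoringConfig()
    x = _check_responses(responses_row, bank)
    theta = _maximize(lambda th: log_likelihood(th, x, bank), config.optimizer_bounds)
    lo, hi = config.optimizer_bounds
    flagged = theta <= lo + 1e-6 or theta >= hi - 1e-6
    if flagged:
        theta = lo if theta <= lo + 1e-6 else hi
        warnings.warn("MLE score pinned at optimizer bound for an extreme pattern")
    obs = [i for i in range(len(bank)) if x[i] != MISSING]
    info = fisher_information(theta, bank, obs)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    return AbilityEstimate(theta=float(theta), se=min(se, 1e6), method="MLE", flagged=flagged)


def score_wle(responses_row, bank: ItemBank, config: ScoringConfig | None = None) -> AbilityEstimate:
    """Weighted-likelihood score: argmax of ``l + 0.5 log I``."""
    config = config or ScoringConfig()
    x = _check_responses(responses_row, bank)
    obs = [i for i in range(len(bank)) if x[i] != MISSING]

    def objective(th: float) -> float:
        info = fisher_information(th, bank, obs)
        return log_likelihood(th, x, bank) + 0.5 * np.log(max(info, 1e-300))

    theta = _maximize(objective, config.optimizer_bounds)
    info = fisher_information(theta, bank, obs)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    return AbilityEstimate(theta=float(theta), se=min(se, 1e6), method="WLE")


def _eap_grid(config: ScoringConfig) -> tuple[np.ndarray, np.ndarray]:
    B = config.truncation_bound
    nodes = np.linspace(-B, B, config.quadrature_points)
    logw = norm.logpdf(nodes, scale=config.prior_sd)
    # trapezoidal end-point halving; interior spacing cancels on normalization
    w = np.exp(logw - logw.max())
    w[0] *= 0.5
    w[-1] *= 0.5
    return nodes, w


def score_eap_truncated(
    responses_row, bank: ItemBank, config: ScoringConfig | None = None
) -> AbilityEstimate:
    """EAP under a truncated-normal prior with compact support ``[-B, B]``."""
    config = config or ScoringConfig()
    x = _check_responses(responses_row, bank)
    nodes, w = _eap_grid(config)
    ll = log_likelihood(nodes, x, bank)
    logpost = np.log(w) + ll
    post = np.exp(logpost - logpost.max())
    post /= post.sum()
    mean = float(post @ nodes)
    var = float(post @ (nodes - mean) ** 2)
    return AbilityEstimate(theta=mean, se=float(np.sqrt(max(var, 0.0))), method="EAP")


def score_mml(
    responses_row, bank: ItemBank, config: ScoringConfig | None = None
) -> AbilityEstimate:
    """Marginal-maximum-likelihood score.

    Alternates maximizing the marginal category likelihood at the current
    score SD with recomputing the SD from the Fisher information, starting
    from the EAP estimate, until the score moves less than
    ``fixed_point_tol``.
    """
    config = config or ScoringConfig()
    x = _check_responses(responses_row, bank)
    obs = [i for i in range(len(bank)) if x[i] != MISSING]
    lam_all, tau_pad, _ = bank.arrays()
    oi = np.asarray(obs)
    lam_o = lam_all[oi]
    lo, up = tau_pad[oi, x[oi] - 1], tau_pad[oi, x[oi]]

    def marginal_loglik(th: float, s: float) -> float:
        p = logistic_normal_cdf(th, s, lam_o, lo) - logistic_normal_cdf(th, s, lam_o, up)
        return float(np.log(np.maximum(p, 1e-12)).sum())

    theta = score_eap_truncated(x, bank, config).theta
    converged = False
    for _ in range(config.max_fixed_point_iters):
        info = fisher_information(theta, bank, obs)
        s = float(1.0 / np.sqrt(max(info, 1e-12)))
        new_theta = _maximize(
            lambda th: marginal_loglik(th, s), config.optimizer_bounds
        )
        if abs(new_theta - theta) < config.fixed_point_tol:
            theta = new_theta
            converged = True
            break
        theta = new_theta
    info = fisher_information(theta, bank, obs)
    se = float(1.0 / np.sqrt(max(info, 1e-12)))
    if not converged:
        warnings.warn("MML scoring fixed point did not converge; returning last iterate")
    return AbilityEstimate(
        theta=float(theta), se=se, method="MML", flagged=not converged
    )


_ESTIMATORS = {
    "mle": score_mle,
    "wle": score_wle,
    "eap": score_eap_truncated,
    "mml": score_mml,
}


def score_all(
    responses: ResponseMatrix,
    bank: ItemBank,
    method: str,
    config: ScoringConfig | None = None,
) -> ScoreTable:
    """Score every person with one estimator, preserving person order.

    Persons with no observed responses are dropped and counted in
    ``n_unscorable``.
    """
    if method not in _ESTIMATORS:
        raise ValueError(
            f"unknown scoring method {method!r}; choose from {sorted(_ESTIMATORS)}"
        )
    responses.validate_against(bank)
    estimator = _ESTIMATORS[method]
    ids: list[str] = []
    out: list[AbilityEstimate] = []
    n_unscorable = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid, row in zip(responses.person_ids, responses.responses):
            if (row == MISSING).all():
                n_unscorable += 1
                continue
            ids.append(pid)
            out.append(estimator(row, bank, config))
    n_flagged = sum(e.flagged for e in out)
    return ScoreTable(
        person_ids=tuple(ids),
        estimates=tuple(out),
        method=method,
        n_flagged=n_flagged,
        n_unscorable=n_unscorable,
    )
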
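"""Independent oracles used by the test suite.

Deliberately written against scipy/textbook definitions, never against the
package's own fast paths: adaptive quadrature for the logistic-normal
integral, dense-grid argmax for the scoring objectives, and term-by-term
density sums for the Bayesian log posterior.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import cauchy, norm


def logistic_normal_quad(theta: float, sigma: float, lam: float, tau: float) -> float:
    """Exact E[expit(lam*(phi - tau))], phi ~ N(theta, sigma^2), by quadrature."""
    if np.isneginf(tau):
        return 1.0
    if np.isposinf(tau):
        return 0.0
    if sigma == 0:
        return float(expit(lam * (theta - tau)))
    val, _err = quad(
        lambda phi: expit(lam * (phi - tau)) * norm.pdf(phi, theta, sigma),
        theta - 10 * sigma,
        theta + 10 * sigma,
        limit=200,
    )
    return float(val)


def marginal_category_quad(theta, sigma, item, j) -> float:
    """Exact Gaussian-smoothed category probability by quadrature."""
    tau = np.concatenate(([-np.inf], item.thresholds, [np.inf]))
    lo = logistic_normal_quad(theta, sigma, item.discrimination, tau[j - 1])
    up = logistic_normal_quad(theta, sigma, item.discrimination, tau[j])
    return lo - up


def grid_argmax(objective, bounds=(-6.0, 6.0), n=24001) -> float:
    """Dense-grid maximizer of a scalar objective."""
    grid = np.linspace(bounds[0], bounds[1], n)
    vals = np.array([objective(t) for t in grid])
    return float(grid[np.argmax(vals)])


def grid_argmax_vec(objective_vec, bounds=(-6.0, 6.0), n=24001) -> float:
    """Same, for objectives that vectorize over the grid."""
    grid = np.linspace(bounds[0], bounds[1], n)
    return float(grid[np.argmax(objective_vec(grid))])


def person_loglik_brute(theta: float, responses, bank) -> float:
    """Sum of log category probabilities, written longhand."""
    total = 0.0
    for x, item in zip(responses, bank.items):
        if x == 0:
            continue
        tau = np.concatenate(([-np.inf], item.thresholds, [np.inf]))
        lam = item.discrimination
        lo = 1.0 if np.isneginf(tau[x - 1]) else expit(lam * (theta - tau[x - 1]))
        up = 0.0 if np.isposinf(tau[x]) else expit(lam * (theta - tau[x]))
        total += np.log(max(lo - up, 1e-12))
    return total


def log_posterior_brute(params, responses, prior) -> float:
    """Term-by-term hierarchical log posterior using scipy densities.

    Half-Cauchy on (0, inf) is cauchy.logpdf + log 2; thresholds carry
    elementwise normal densities under the ordering constraint.
    """
    lam = np.asarray(params.lam, float)
    lp = 0.0
    for p in range(len(params.theta)):
        lp += person_loglik_brute(
            params.theta[p], responses.responses[p], _BankView(lam, params.thresholds)
        )
    for lam_i in lam:
        lp += cauchy.logpdf(lam_i, 0, prior.discrimination_scale) + np.log(2.0)
    for thr in params.thresholds:
        lp += norm.logpdf(np.asarray(thr), params.mu_tau, params.sigma_tau).sum()
    lp += norm.logpdf(params.mu_tau, 0, prior.threshold_mean_scale)
    lp += cauchy.logpdf(params.sigma_tau, 0, prior.threshold_sd_scale) + np.log(2.0)
    lp += norm.logpdf(np.asarray(params.theta), 0, params.sigma).sum()
    lp += cauchy.logpdf(params.sigma, 0, prior.ability_sd_scale) + np.log(2.0)
    return float(lp)


class _BankView:
    """Minimal bank-shaped adapter for person_loglik_brute."""

    def __init__(self, lam, thresholds):
        self.items = [
            _ItemView(l, t) for l, t in zip(lam, thresholds)
        ]


class _ItemView:
    def __init__(self, lam, thr):
        self.discrimination = float(lam)
        self.thresholds = np.asarray(thr, float)
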
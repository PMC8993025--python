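"""Regularized fully-Bayesian calibration of the graded response model.

Hierarchical model
------------------
::

    X_pi  ~ categorical(GRM(theta_p; lambda_i, tau_i))
    lambda_i ~ half-Cauchy(0, 5)
    tau_{i,j} ~ normal(mu_tau, sigma_tau), ordered within each item
    mu_tau ~ normal(0, 5)
    sigma_tau ~ half-Cauchy(0, 1)
    theta_p ~ normal(0, sigma)
    sigma ~ half-Cauchy(0, 1)

The ordering constraint on thresholds is realized by an order-preserving
transform (first element free, log increments) with the matching Jacobian
correction; positive scales are log-parameterized.  Sampling is
Hamiltonian Monte Carlo with dual-averaging step-size adaptation and a
diagonal mass matrix estimated during warmup, written directly against
analytic gradients of the log posterior (no external PPL).  A mean-field
variational fallback is available behind ``SamplerConfig(method="advi")``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .grm import (
    MISSING,
    AbilityEstimate,
    ItemBank,
    ItemParameters,
    ResponseMatrix,
)

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "ParameterSet",
    "PosteriorDraws",
    "ConvergenceDiagnostics",
    "log_posterior",
    "sample_posterior",
    "point_estimates",
]

_LOG_2_PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Scales of the weakly-informative priors."""

    discrimination_scale: float = 5.0
    threshold_mean_scale: float = 5.0
    threshold_sd_scale: float = 1.0
    ability_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "discrimination_scale",
            "threshold_mean_scale",
            "threshold_sd_scale",
            "ability_sd_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; all randomness flows from ``seed``."""

    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    leapfrog_steps: int = 16
    target_accept: float = 0.8
    seed: int = 0
    method: str = "hmc"  # or "advi"
    advi_iters: int = 3000
    max_rhat: float = 1.05

    def __post_init__(self) -> None:
        if self.method not in {"hmc", "advi"}:
            raise ValueError("method must be 'hmc' or 'advi'")
        if self.chains < 1 or self.draws < 1:
            raise ValueError("chains and draws must be >= 1")


@dataclass(frozen=True)
class ParameterSet:
    """One draw's parameters on the constrained (natural) scale."""

    lam: np.ndarray  # (I,)
    thresholds: tuple[np.ndarray, ...]  # per item, ordered
    mu_tau: float
    sigma_tau: float
    sigma: float
    theta: np.ndarray  # (P,)


@dataclass(frozen=True)
class PosteriorDraws:
    """Constrained-scale posterior draws, ``(chain, draw, ...)`` arrays."""

    lam: np.ndarray  # (C, D, I)
    tau_flat: np.ndarray  # (C, D, T) thresholds concatenated across items
    mu_tau: np.ndarray  # (C, D)
    sigma_tau: np.ndarray  # (C, D)
    sigma: np.ndarray  # (C, D)
    theta: np.ndarray  # (C, D, P)
    item_ids: tuple[str, ...]
    person_ids: tuple[str, ...]
    n_categories: np.ndarray
    seed: int

    @property
    def item_slices(self) -> list[slice]:
        edges = np.concatenate(([0], np.cumsum(self.n_categories - 1)))
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def to_dict(self) -> dict[str, np.ndarray]:
        return {
            "lam": self.lam,
            "tau": self.tau_flat,
            "mu_tau": self.mu_tau,
            "sigma_tau": self.sigma_tau,
            "sigma": self.sigma,
            "theta": self.theta,
        }


@dataclass(frozen=True)
class ConvergenceDiagnostics:
    rhat: dict[str, np.ndarray]
    ess: dict[str, np.ndarray]
    divergences: int
    converged: bool


def _half_cauchy_logpdf(x, scale: float):
    return math.log(2.0 / (math.pi * scale)) - np.log1p((x / scale) ** 2)


def log_posterior(
    params: ParameterSet,
    responses: ResponseMatrix,
    prior: PriorConfig | None = None,
) -> float:
    """Unnormalized log posterior density on the constrained scale.

    Returns ``-inf`` (never raises) when a support constraint is violated:
    non-positive ``lambda``/``sigma``/``sigma_tau`` or unordered thresholds.
    """
    prior = prior or PriorConfig()
    lam = np.asarray(params.lam, dtype=float)
    theta = np.asarray(params.theta, dtype=float)
    if (lam <= 0).any() or params.sigma <= 0 or params.sigma_tau <= 0:
        return -np.inf
    for thr in params.thresholds:
        if np.asarray(thr).size > 1 and (np.diff(thr) <= 0).any():
            return -np.inf

    X = responses.responses
    lp = 0.0
    for i, thr in enumerate(params.thresholds):
        tau_pad = np.concatenate(([-np.inf], np.asarray(thr, float), [np.inf]))
        col = X[:, i]
        obs = col != MISSING
        if obs.any():
            F = expit(lam[i] * (theta[obs, None] - tau_pad[None, :]))
            F[:, 0], F[:, -1] = 1.0, 0.0
            idx = col[obs] - 1
            rows = np.arange(idx.size)
            p = F[rows, idx] - F[rows, idx + 1]
            if (p <= 0).any():
                return -np.inf
            lp += float(np.log(p).sum())
        # threshold prior: each element normal(mu_tau, sigma_tau)
        tarr = np.asarray(thr, float)
        lp += float(
            (-0.5 * _LOG_2_PI - math.log(params.sigma_tau)
             - 0.5 * ((tarr - params.mu_tau) / params.sigma_tau) ** 2).sum()
        )
    lp += float(_half_cauchy_logpdf(lam, prior.discrimination_scale).sum())
    s = prior.threshold_mean_scale
    lp += -0.5 * _LOG_2_PI - math.log(s) - 0.5 * (params.mu_tau / s) ** 2
    lp += float(_half_cauchy_logpdf(params.sigma_tau, prior.threshold_sd_scale))
    if theta.size:
        lp += float(
            (-0.5 * _LOG_2_PI - math.log(params.sigma)
             - 0.5 * (theta / params.sigma) ** 2).sum()
        )
    lp += float(_half_cauchy_logpdf(params.sigma, prior.ability_sd_scale))
    return lp


# ---------------------------------------------------------------------------
# unconstrained-space target with analytic gradients
# ---------------------------------------------------------------------------


class _Target:
    """Log density and gradient on the unconstrained parameter vector.

    Layout of ``z``: ``[a (I), t (T), mu_tau, log sigma_tau, log sigma,
    theta (P)]`` where ``lambda = exp(a)`` and each item's thresholds are
    ``(t_1, t_1 + exp(t_2), ...)``.  Includes the log-Jacobians of all
    transforms, so HMC on ``z`` targets the constrained posterior.
    """

    def __init__(self, responses: ResponseMatrix, ncat: np.ndarray, prior: PriorConfig):
        X = responses.responses
        self.P, self.I = X.shape
        self.ncat = ncat
        self.prior = prior
        self.T = int((ncat - 1).sum())
        edges = np.concatenate(([0], np.cumsum(ncat - 1)))
        self.slices = [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
        # mask of "is an increment" (log-transformed) threshold coordinate
        inc = np.ones(self.T, dtype=bool)
        inc[edges[:-1]] = False
        self.inc_mask = inc
        self.dim = self.I + self.T + 3 + self.P

        self.jmax = int(ncat.max())
        obs = X != MISSING
        self.obs = obs
        self.n_obs = int(obs.sum())
        # flat (p, i) observation lists for gather/scatter
        pp, ii = np.nonzero(obs)
        self.o_p, self.o_i = pp, ii
        x = X[pp, ii]
        w = self.jmax + 1
        self.lo_flat = ii * w + (x - 1)  # index into padded tau, lower cut
        self.up_flat = ii * w + x
        # map padded columns 1..J-1 of each item into flat threshold vector
        pad2flat = np.full(self.I * w, -1, dtype=np.int64)
        for i in range(self.I):
            k = ncat[i] - 1
            pad2flat[i * w + 1 : i * w + ncat[i]] = np.arange(
                edges[i], edges[i] + k
            )
        self.pad2flat = pad2flat

    # -- transforms ---------------------------------------------------------

    def split(self, z: np.ndarray):
        I, T = self.I, self.T
        a = z[:I]
        t = z[I : I + T]
        mu_tau = z[I + T]
        ls_tau = z[I + T + 1]
        ls = z[I + T + 2]
        theta = z[I + T + 3 :]
        return a, t, mu_tau, ls_tau, ls, theta

    def tau_from_free(self, t: np.ndarray) -> np.ndarray:
        """Flat ordered thresholds from free coordinates."""
        v = np.where(self.inc_mask, np.exp(t), t)
        out = np.empty_like(v)
        for sl in self.slices:
            out[sl] = np.cumsum(v[sl])
        return out

    def constrained(self, z: np.ndarray) -> ParameterSet:
        a, t, mu_tau, ls_tau, ls, theta = self.split(z)
        tau = self.tau_from_free(t)
        return ParameterSet(
            lam=np.exp(a),
            thresholds=tuple(tau[sl].copy() for sl in self.slices),
            mu_tau=float(mu_tau),
            sigma_tau=float(np.exp(ls_tau)),
            sigma=float(np.exp(ls)),
            theta=theta.copy(),
        )

    def initial(self, responses: ResponseMatrix, rng: np.random.Generator) -> np.ndarray:
        """Data-informed start: unit slopes, frequency-quantile thresholds,
        abilities at standardized raw scores (keeps chains near the sigma=1
        scale convention instead of the degenerate end of the scale ridge)."""
        from .mml import _initial_item  # shared start-value heuristic

        z = np.zeros(self.dim)
        X = responses.responses
        for i, sl in enumerate(self.slices):
            k = self.ncat[i] - 1
            if self.P:
                z[self.I + sl.start : self.I + sl.stop] = _initial_item(
                    X[:, i], self.ncat[i]
                )[1:]
            elif k > 1:
                # prior-only: evenly spaced start between -1 and 1
                z[self.I + sl.start] = -1.0
                z[self.I + sl.start + 1 : self.I + sl.stop] = math.log(2.0 / (k - 1))
        if self.P:
            obs = self.obs
            with np.errstate(invalid="ignore"):
                raw = np.where(obs, X, 0).sum(axis=1) / np.maximum(obs.sum(axis=1), 1)
            sd = raw.std()
            theta0 = (raw - raw.mean()) / sd if sd > 0 else np.zeros(self.P)
            z[self.I + self.T + 3 :] = np.clip(theta0, -3.0, 3.0)
        z += rng.normal(0.0, 0.01, size=self.dim)
        return z

    # -- value and gradient -------------------------------------------------

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        # a runaway leapfrog trajectory is a divergence, not an exception
        if not np.all(np.isfinite(z)) or np.abs(z).max() > 60.0:
            return -np.inf, np.zeros_like(z)
        with np.errstate(all="ignore"):
            lp, grad = self._logp_grad_inner(z)
        if not (np.isfinite(lp) and np.all(np.isfinite(grad))):
            return -np.inf, np.zeros_like(z)
        return lp, grad

    def _logp_grad_inner(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        I, T, P = self.I, self.T, self.P
        a, t, mu_tau, ls_tau, ls, theta = self.split(z)
        lam = np.exp(a)
        sigma_tau = math.exp(ls_tau)
        sigma = math.exp(ls)
        tau = self.tau_from_free(t)
        w = self.jmax + 1
        tau_pad = np.full(I * w, np.inf)
        tau_pad[::w] = -np.inf
        valid = self.pad2flat >= 0
        tau_pad[valid] = tau[self.pad2flat[valid]]

        grad = np.zeros_like(z)
        lp = 0.0

        # --- likelihood over observed (p, i) pairs
        g_tau = np.zeros(T)
        g_theta = np.zeros(P)
        g_lam = np.zeros(I)
        if self.n_obs:
            th = theta[self.o_p]
            lm = lam[self.o_i]
            lo = tau_pad[self.lo_flat]
            up = tau_pad[self.up_flat]
            F_lo = expit(lm * (th - lo))
            F_up = expit(lm * (th - up))
            p_resp = np.maximum(F_lo - F_up, 1e-300)
            lp += float(np.log(p_resp).sum())
            winv = 1.0 / p_resp
            u_lo = F_lo * (1.0 - F_lo)
            u_up = F_up * (1.0 - F_up)
            np.add.at(g_theta, self.o_p, lm * (u_lo - u_up) * winv)
            z_lo = (th - np.where(np.isfinite(lo), lo, th)) * u_lo
            z_up = (th - np.where(np.isfinite(up), up, th)) * u_up
            np.add.at(g_lam, self.o_i, (z_lo - z_up) * winv)
            # scatter into flat threshold gradient (skip virtual boundaries)
            contrib_lo = -lm * u_lo * winv
            contrib_up = lm * u_up * winv
            fl, fu = self.pad2flat[self.lo_flat], self.pad2flat[self.up_flat]
            m = fl >= 0
            g_tau += np.bincount(fl[m], weights=contrib_lo[m], minlength=T)
            m = fu >= 0
            g_tau += np.bincount(fu[m], weights=contrib_up[m], minlength=T)

        # --- priors (constrained scale) + Jacobians
        pc = self.prior
        # lambda ~ half-Cauchy(0, s_l); Jacobian: + a
        s_l = pc.discrimination_scale
        lp += float(_half_cauchy_logpdf(lam, s_l).sum()) + float(a.sum())
        grad[:I] = (g_lam * lam) - 2.0 * lam**2 / (s_l**2 + lam**2) + 1.0
        # thresholds ~ normal(mu_tau, sigma_tau)
        resid = tau - mu_tau
        lp += float(
            -0.5 * T * _LOG_2_PI - T * math.log(sigma_tau)
            - 0.5 * float((resid**2).sum()) / sigma_tau**2
        )
        g_tau += -resid / sigma_tau**2
        # Jacobian of log-increment transform
        lp += float(t[self.inc_mask].sum())
        # chain rule: free coord k collects d/dtau of all later thresholds in item
        g_t = np.empty(T)
        for sl in self.slices:
            tail = np.cumsum(g_tau[sl][::-1])[::-1]
            g_t[sl] = tail
        g_t = np.where(self.inc_mask, g_t * np.exp(t) + 1.0, g_t)
        grad[I : I + T] = g_t
        # mu_tau ~ normal(0, s_m)
        s_m = pc.threshold_mean_scale
        lp += -0.5 * _LOG_2_PI - math.log(s_m) - 0.5 * (mu_tau / s_m) ** 2
        grad[I + T] = float(resid.sum()) / sigma_tau**2 - mu_tau / s_m**2
        # sigma_tau ~ half-Cauchy(0, s_t), log-parameterized
        s_t = pc.threshold_sd_scale
        lp += float(_half_cauchy_logpdf(sigma_tau, s_t)) + ls_tau
        grad[I + T + 1] = (
            float((resid**2).sum()) / sigma_tau**2
            - T
            - 2.0 * sigma_tau**2 / (s_t**2 + sigma_tau**2)
            + 1.0
        )
        # theta ~ normal(0, sigma); sigma ~ half-Cauchy(0, s_a)
        s_a = pc.ability_sd_scale
        lp += float(_half_cauchy_logpdf(sigma, s_a)) + ls
        grad[I + T + 2] = -2.0 * sigma**2 / (s_a**2 + sigma**2) + 1.0
        if P:
            lp += float(
                -0.5 * P * _LOG_2_PI - P * math.log(sigma)
                - 0.5 * float((theta**2).sum()) / sigma**2
            )
            g_theta += -theta / sigma**2
            grad[I + T + 2] += float((theta**2).sum()) / sigma**2 - P
            grad[I + T + 3 :] = g_theta
        return lp, grad


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


def _hmc_chain(
    target: _Target,
    z0: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One HMC chain; returns (draws, n_divergences)."""
    dim = target.dim
    warm, draws = config.warmup, config.draws
    inv_mass = np.ones(dim)
    eps = 0.1
    # dual averaging state
    mu_da = math.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    # mass adaptation window (Welford)
    w_lo, w_hi = int(0.15 * warm), int(0.8 * warm)
    count, mean_acc, m2_acc = 0, np.zeros(dim), np.zeros(dim)

    z = z0.copy()
    lp, grad = target.logp_grad(z)
    out = np.empty((draws, dim))
    divergences = 0
    total = warm + draws
    steps0 = config.leapfrog_steps
    for it in range(total):
        r = rng.normal(size=dim) / np.sqrt(inv_mass)
        steps = rng.integers(max(1, steps0 // 2), int(1.5 * steps0) + 1)
        z_new, r_new = z.copy(), r.copy()
        lp_new, grad_new = lp, grad
        h0 = -lp + 0.5 * float(r @ (inv_mass * r))
        diverged = False
        r_new = r_new + 0.5 * eps * grad_new
        for s in range(steps):
            z_new = z_new + eps * inv_mass * r_new
            lp_new, grad_new = target.logp_grad(z_new)
            if not np.isfinite(lp_new):
                diverged = True
                break
            r_new = r_new + (eps if s < steps - 1 else 0.5 * eps) * grad_new
        if diverged:
            accept_prob = 0.0
        else:
            h1 = -lp_new + 0.5 * float(r_new @ (inv_mass * r_new))
            dh = h1 - h0
            if dh > 1000.0:
                diverged = True
                accept_prob = 0.0
            else:
                accept_prob = min(1.0, math.exp(-max(dh, -700.0)))
        if accept_prob > 0 and rng.random() < accept_prob:
            z, lp, grad = z_new, lp_new, grad_new
        if it < warm:
            # dual averaging
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (
                config.target_accept - accept_prob
            ) / (m + t0)
            log_eps = mu_da - math.sqrt(m) / gamma * h_bar
            eta = m ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = math.exp(log_eps)
            if w_lo <= it < w_hi:
                count += 1
                delta = z - mean_acc
                mean_acc += delta / count
                m2_acc += delta * (z - mean_acc)
            if it == w_hi - 1 and count > 10:
                var = m2_acc / max(count - 1, 1)
                # Stan-style regularization toward unit mass
                inv_mass = var * (count / (count + 5.0)) + 1e-3 * (5.0 / (count + 5.0))
                # restart step-size adaptation around the current value
                mu_da = math.log(10 * eps)
                log_eps_bar, h_bar = math.log(eps), 0.0
            if it == warm - 1:
                eps = math.exp(log_eps_bar)
        else:
            if diverged:
                divergences += 1
            out[it - warm] = z
    return out, divergences


def _advi(
    target: _Target,
    z0: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean-field Gaussian variational fit; returns pseudo-draws (draws, dim)."""
    dim = target.dim
    mu = z0.copy()
    omega = np.full(dim, -2.0)  # log sd
    m_mu = np.zeros(dim)
    v_mu = np.zeros(dim)
    m_om = np.zeros(dim)
    v_om = np.zeros(dim)
    lr, b1, b2, eps_adam = 0.02, 0.9, 0.999, 1e-8
    for it in range(1, config.advi_iters + 1):
        eta = rng.normal(size=dim)
        zs = mu + np.exp(omega) * eta
        lp, grad = target.logp_grad(zs)
        if not np.isfinite(lp):
            continue
        g_mu = grad
        g_om = grad * eta * np.exp(omega) + 1.0  # + entropy gradient
        for g, mq, vq, param in (
            (g_mu, m_mu, v_mu, mu),
            (g_om, m_om, v_om, omega),
        ):
            mq *= b1
            mq += (1 - b1) * g
            vq *= b2
            vq += (1 - b2) * g * g
            mhat = mq / (1 - b1**it)
            vhat = vq / (1 - b2**it)
            param += lr * mhat / (np.sqrt(vhat) + eps_adam)
    return mu + np.exp(omega) * rng.normal(size=(config.draws, dim))


def sample_posterior(
    responses: ResponseMatrix,
    prior: PriorConfig | None = None,
    config: SamplerConfig | None = None,
    *,
    n_categories: np.ndarray | None = None,
    standardize: bool = True,
) -> tuple[PosteriorDraws, ConvergenceDiagnostics]:
    """Sample the hierarchical GRM posterior.

    Category counts are inferred from the data unless ``n_categories`` is
    given (required for prior-only runs with zero persons).  The result is
    flagged non-converged when any item parameter's split R-hat exceeds
    ``config.max_rhat``.

    With ``standardize=True`` (default) every draw is mapped to the
    unit-ability frame: the likelihood is exactly invariant under
    ``(theta, tau) -> c*(theta, tau)``, ``lambda -> lambda/c``, so the
    population scale is only softly identified through the priors; each
    draw is rescaled by its own ability SD so that reported item and person
    parameters live on the same unit-population scale that MML imposes.
    Scale-invariant likelihood functionals are unaffected.  Skipped for
    prior-only runs (no persons).
    """
    import arviz as az

    prior = prior or PriorConfig()
    config = config or SamplerConfig()
    if n_categories is None:
        from .mml import _infer_categories

        n_categories = _infer_categories(responses)
    ncat = np.asarray(n_categories, dtype=int)
    target = _Target(responses, ncat, prior)

    chain_draws = []
    divergences = 0
    for c in range(config.chains):
        rng = np.random.default_rng([config.seed, c])
        z0 = target.initial(responses, rng)
        if config.method == "hmc":
            zs, ndiv = _hmc_chain(target, z0, config, rng)
            divergences += ndiv
        else:
            zs = _advi(target, z0, config, rng)
        chain_draws.append(zs)
    Z = np.stack(chain_draws)  # (C, D, dim)

    I, T, P = target.I, target.T, target.P
    C, D = Z.shape[:2]
    lam = np.exp(Z[..., :I])
    tau = np.empty((C, D, T))
    tfree = Z[..., I : I + T]
    v = np.where(target.inc_mask, np.exp(tfree), tfree)
    for sl in target.slices:
        tau[..., sl] = np.cumsum(v[..., sl], axis=-1)
    mu_tau = Z[..., I + T].copy()
    sigma_tau = np.exp(Z[..., I + T + 1])
    sigma = np.exp(Z[..., I + T + 2])
    theta = Z[..., I + T + 3 :].copy()
    if standardize and P > 1:
        s = theta.std(axis=-1, ddof=0)  # (C, D) per-draw ability scale
        lam = lam * s[..., None]
        tau = tau / s[..., None]
        theta = theta / s[..., None]
        mu_tau = mu_tau / s
        sigma_tau = sigma_tau / s
        sigma = sigma / s
    draws = PosteriorDraws(
        lam=lam,
        tau_flat=tau,
        mu_tau=mu_tau,
        sigma_tau=sigma_tau,
        sigma=sigma,
        theta=theta,
        item_ids=tuple(responses.item_ids),
        person_ids=tuple(responses.person_ids),
        n_categories=ncat,
        seed=config.seed,
    )

    rhat: dict[str, np.ndarray] = {}
    ess: dict[str, np.ndarray] = {}
    import logging

    logging.getLogger("arviz").setLevel(logging.ERROR)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in draws.to_dict().items():
            if arr.ndim == 2:
                arr = arr[..., None]
            if arr.shape[-1] == 0:
                rhat[name] = np.empty(0)
                ess[name] = np.empty(0)
                continue
            rhat[name] = np.array(
                [float(az.rhat(arr[:, :, k])) for k in range(arr.shape[-1])]
            )
            ess[name] = np.array(
                [float(az.ess(arr[:, :, k])) for k in range(arr.shape[-1])]
            )
    item_rhats = np.concatenate([rhat["lam"], rhat["tau"]])
    ok = np.isfinite(item_rhats)
    converged = bool((item_rhats[ok] <= config.max_rhat).all()) if ok.any() else True
    diag = ConvergenceDiagnostics(
        rhat=rhat, ess=ess, divergences=divergences, converged=converged
    )
    if not converged:
        warnings.warn(
            f"posterior sampling flagged non-converged: max item R-hat = "
            f"{np.nanmax(item_rhats):.3f}"
        )
    return draws, diag


def point_estimates(
    draws: PosteriorDraws,
    diagnostics: ConvergenceDiagnostics | None = None,
    *,
    estimator: str = "mean",
    domain: str = "bayes",
) -> tuple[ItemBank, tuple[AbilityEstimate, ...]]:
    """Posterior point summaries: an ItemBank and per-person estimates.

    ``estimator="mean"`` (L2 loss, the default) or ``"median"``.  Threshold
    ordering survives both summaries, since every draw is ordered.  Person
    standard errors are posterior SDs of ``theta_p``.
    """
    if estimator not in {"mean", "median"}:
        raise ValueError("estimator must be 'mean' or 'median'")
    if diagnostics is not None and not diagnostics.converged:
        warnings.warn("point estimates from a non-converged posterior")
    agg = np.mean if estimator == "mean" else np.median
    lam_hat = agg(draws.lam, axis=(0, 1))
    tau_hat = agg(draws.tau_flat, axis=(0, 1))
    items = tuple(
        ItemParameters(
            item_id=draws.item_ids[i],
            n_categories=int(draws.n_categories[i]),
            discrimination=float(lam_hat[i]),
            thresholds=tuple(tau_hat[sl]),
        )
        for i, sl in enumerate(draws.item_slices)
    )
    bank = ItemBank(domain=domain, items=items)
    theta_hat = agg(draws.theta, axis=(0, 1))
    theta_sd = draws.theta.std(axis=(0, 1), ddof=1) if draws.theta.size else np.empty(0)
    persons = tuple(
        AbilityEstimate(theta=float(m), se=float(s), method="CALIBRATION")
        for m, s in zip(theta_hat, theta_sd)
    )
    return bank, persons
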
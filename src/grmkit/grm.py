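"""Graded response model kernels.

Probability curves, log-likelihood, Fisher information and the
logistic-normal (probit-scaled) cumulative approximation that calibration,
scoring and evaluation all build on.

Conventions
-----------
Response codes are 1-based: item ``i`` with ``J_i`` categories takes codes
``1..J_i``.  Missing responses are encoded with the sentinel :data:`MISSING`
(0), never a valid code.  Each item stores ``J_i - 1`` free thresholds; the
virtual boundary thresholds ``tau_1 = -inf`` and ``tau_{J+1} = +inf`` are
exposed internally so that category probabilities telescope without
special-casing the first and last category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "MISSING",
    "PROB_FLOOR",
    "ItemParameters",
    "ItemBank",
    "ResponseMatrix",
    "AbilityEstimate",
    "cumulative_prob",
    "category_prob",
    "log_likelihood",
    "fisher_information",
    "logistic_normal_cdf",
    "marginal_category_prob",
    "tail_odds",
]

#: Sentinel for a missing ordinal response (0 is never a valid 1-based code).
MISSING = 0

#: Default floor applied to probabilities before taking logs, keeping
#: deviance finite for extreme response patterns.
PROB_FLOOR = 1e-12

#: Probit scaling constant: the logistic sigmoid is approximated by
#: Phi(c * x).  The classical minimax choice c = 1/1.702 (the IRT
#: "D = 1.702" scaling) keeps the absolute error below 0.0095 everywhere;
#: the derivative-matched alternative sqrt(pi/8) roughly doubles it.
PROBIT_SCALE = 1.0 / 1.702


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of a single graded-response item.

    Parameters
    ----------
    item_id
        Unique identifier within a bank.
    n_categories
        Number of ordered response categories ``J >= 2``.
    discrimination
        Positive logit slope.
    thresholds
        ``J - 1`` strictly increasing cut points on the ability scale.
    """

    item_id: str
    n_categories: int
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"item {self.item_id!r}: n_categories must be >= 2")
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise ValueError(f"item {self.item_id!r}: discrimination must be > 0")
        thr = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "thresholds", thr)
        if len(thr) != self.n_categories - 1:
            raise ValueError(
                f"item {self.item_id!r}: expected {self.n_categories - 1} "
                f"thresholds, got {len(thr)}"
            )
        if not all(np.isfinite(thr)):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError(
                f"item {self.item_id!r}: thresholds must be strictly increasing"
            )

    def padded_thresholds(self) -> np.ndarray:
        """Thresholds with the virtual ``-inf`` / ``+inf`` boundaries attached."""
        return np.concatenate(([-np.inf], self.thresholds, [np.inf]))


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of calibrated items for one domain."""

    domain: str
    items: tuple[ItemParameters, ...]

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise ValueError("item bank must contain at least one item")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("item ids must be unique within a bank")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([it.n_categories for it in self.items])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense ``(discriminations, padded thresholds, n_categories)``.

        The threshold matrix has shape ``(I, max_J + 1)``; column 0 is
        ``-inf`` and columns at or beyond each item's ``J_i`` are ``+inf``,
        so row ``i`` column ``j`` holds ``tau_{i, j+1}``.
        """
        lam = np.array([it.discrimination for it in self.items])
        ncat = self.n_categories
        jmax = int(ncat.max())
        tau = np.full((len(self.items), jmax + 1), np.inf)
        tau[:, 0] = -np.inf
        for i, it in enumerate(self.items):
            tau[i, 1 : it.n_categories] = it.thresholds
        return lam, tau, ncat


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items ordinal responses with explicit missingness.

    ``responses[p, i]`` is the 1-based code of person ``p`` on item ``i`` or
    :data:`MISSING`.
    """

    person_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    responses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "person_ids", tuple(str(p) for p in self.person_ids))
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        resp = np.asarray(self.responses, dtype=np.int64)
        object.__setattr__(self, "responses", resp)
        if resp.shape != (len(self.person_ids), len(self.item_ids)):
            raise ValueError(
                f"responses shape {resp.shape} does not match "
                f"{len(self.person_ids)} persons x {len(self.item_ids)} items"
            )
        if len(set(self.person_ids)) != len(self.person_ids):
            raise ValueError("duplicate person_id")
        if resp.size and resp.min() < 0:
            raise ValueError("response codes must be >= 0 (0 = missing)")

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def observed_mask(self) -> np.ndarray:
        return self.responses != MISSING

    def validate_against(self, bank: ItemBank) -> None:
        """Check item alignment and code ranges against a bank."""
        if list(self.item_ids) != bank.item_ids:
            missing = set(bank.item_ids) - set(self.item_ids)
            extra = set(self.item_ids) - set(bank.item_ids)
            raise ValueError(
                "response matrix items do not match bank: "
                f"missing from matrix: {sorted(missing)}; "
                f"unknown to bank: {sorted(extra)}"
            )
        ncat = bank.n_categories
        bad = self.responses > ncat[None, :]
        if bad.any():
            p, i = np.argwhere(bad)[0]
            raise ValueError(
                f"response code {self.responses[p, i]} out of range for item "
                f"{self.item_ids[i]!r} (J={ncat[i]}) at person {self.person_ids[p]!r}"
            )

    def subset_persons(self, index: np.ndarray) -> "ResponseMatrix":
        index = np.asarray(index)
        return ResponseMatrix(
            person_ids=tuple(np.asarray(self.person_ids, dtype=object)[index]),
            item_ids=self.item_ids,
            responses=self.responses[index],
        )


@dataclass(frozen=True)
class AbilityEstimate:
    """A scored person: point estimate, standard error and provenance tag."""

    theta: float
    se: float
    method: str
    flagged: bool = False

    _METHODS = frozenset({"MLE", "WLE", "EAP", "MML", "CALIBRATION"})

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if self.se < 0 or not np.isfinite(self.se):
            raise ValueError("se must be finite and >= 0")


# ---------------------------------------------------------------------------
# probability kernels
# ---------------------------------------------------------------------------


def cumulative_prob(theta, item: ItemParameters, j: int):
    """``Pr(X >= j | theta)`` for category index ``j`` in ``1..J+1``.

    Boundary conventions: ``j = 1`` returns 1 exactly, ``j = J + 1``
    returns 0 exactly.  Vectorized over ``theta``.
    """
    if not 1 <= j <= item.n_categories + 1:
        raise IndexError(
            f"category index {j} out of range 1..{item.n_categories + 1}"
        )
    theta = np.asarray(theta, dtype=float)
    if j == 1:
        return np.ones_like(theta) if theta.ndim else 1.0
    if j == item.n_categories + 1:
        return np.zeros_like(theta) if theta.ndim else 0.0
    tau = item.thresholds[j - 2]
    out = expit(item.discrimination * (theta - tau))
    return out if theta.ndim else float(out)


def category_prob(theta, item: ItemParameters) -> np.ndarray:
    """Probability vector over categories ``1..J`` at ability ``theta``.

    Entry ``j`` is ``Pr(X >= j) - Pr(X >= j+1)``.  For array ``theta`` the
    category axis is appended last.
    """
    theta = np.asarray(theta, dtype=float)
    tau = item.padded_thresholds()
    cum = expit(item.discrimination * (theta[..., None] - tau))
    cum[..., 0] = 1.0
    cum[..., -1] = 0.0
    return -np.diff(cum, axis=-1)


def log_likelihood(
    theta,
    responses: Sequence[int] | np.ndarray,
    bank: ItemBank,
    *,
    floor: float = PROB_FLOOR,
):
    """GRM log-likelihood of one person's responses, vectorized over theta.

    ``responses`` is aligned with ``bank.items``; entries equal to
    :data:`MISSING` contribute nothing.  Probabilities are floored at
    ``floor`` before the log.

    Raises
    ------
    ValueError
        If every response is missing (the person is unscorable).
    """
    x = np.asarray(responses, dtype=np.int64)
    if x.shape != (len(bank),):
        raise ValueError(f"expected {len(bank)} responses, got shape {x.shape}")
    obs = x != MISSING
    if not obs.any():
        raise ValueError("person has no observed responses; cannot be scored")
    theta = np.asarray(theta, dtype=float)
    lam, tau, ncat = bank.arrays()
    if (x > ncat).any():
        i = int(np.argmax(x > ncat))
        raise ValueError(
            f"response code {x[i]} invalid for item {bank.item_ids[i]!r}"
        )
    idx = np.flatnonzero(obs)
    lo = tau[idx, x[idx] - 1]
    up = tau[idx, x[idx]]
    lam_o = lam[idx]
    t = theta[..., None]
    p = expit(lam_o * (t - lo)) - expit(lam_o * (t - up))
    out = np.log(np.maximum(p, floor)).sum(axis=-1)
    return out if theta.ndim else float(out)


def fisher_information(theta, bank: ItemBank, items: Sequence[int] | None = None):
    """Expected (Fisher) information ``I(theta)`` of a bank or item subset.

    ``sum_i sum_j (dP_ij/dtheta)^2 / P_ij``; additive over items.  An empty
    subset yields 0 with a warning.
    """
    if items is None:
        subset = list(range(len(bank)))
    else:
        subset = list(items)
    theta = np.asarray(theta, dtype=float)
    if not subset:
        import warnings

        warnings.warn("fisher_information over an empty item subset is 0")
        return np.zeros_like(theta) if theta.ndim else 0.0
    total = np.zeros(np.shape(theta))
    for i in subset:
        item = bank.items[i]
        lam = item.discrimination
        tau = item.padded_thresholds()
        cum = expit(lam * (theta[..., None] - tau))
        cum[..., 0] = 1.0
        cum[..., -1] = 0.0
        u = cum * (1.0 - cum)  # F(1-F); exactly 0 at the virtual boundaries
        p = -np.diff(cum, axis=-1)
        dp = lam * -np.diff(u, axis=-1)
        total = total + np.where(p > 0, dp * dp / np.maximum(p, 1e-300), 0.0).sum(
            axis=-1
        )
    return total if theta.ndim else float(total)


def logistic_normal_cdf(theta, sigma, lam, tau):
    """Gaussian-smoothed logistic cumulative curve.

    Approximates ``int expit(lam * (phi - tau)) dN(phi; theta, sigma^2)``
    by the closed form ``Phi(c*lam*(theta - tau) / sqrt(1 + c^2*lam^2*sigma^2))``
    with the minimax logistic-probit constant ``c = 1/1.702``.

    ``tau = -inf`` returns 1 and ``tau = +inf`` returns 0 exactly.
    Vectorized over all arguments by broadcasting.
    """
    sigma = np.asarray(sigma, dtype=float)
    if (sigma < 0).any():
        raise ValueError("sigma must be >= 0")
    theta = np.asarray(theta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    tau_arr = np.asarray(tau, dtype=float)
    c = PROBIT_SCALE
    denom = np.sqrt(1.0 + (c * lam * sigma) ** 2)
    with np.errstate(invalid="ignore"):
        z = c * lam * (theta - tau_arr) / denom
    # resolve the inf - inf cases introduced by the virtual boundaries
    z = np.where(tau_arr == -np.inf, np.inf, z)
    z = np.where(tau_arr == np.inf, -np.inf, z)
    out = ndtr(z)
    scalar = all(np.ndim(a) == 0 for a in (theta, sigma, lam, tau))
    return float(out) if scalar else out


def marginal_category_prob(
    theta_hat,
    se,
    item: ItemParameters,
    j: int | None = None,
    *,
    floor: float = PROB_FLOOR,
):
    """Category probability under the Gaussian ability approximation.

    Difference of :func:`logistic_normal_cdf` at the category's bracketing
    thresholds, floored at ``floor``.  With ``j=None`` the full vector over
    ``1..J`` is returned (category axis last).
    """
    tau = item.padded_thresholds()
    if j is not None:
        if not 1 <= j <= item.n_categories:
            raise IndexError(f"category {j} out of range 1..{item.n_categories}")
        lo = logistic_normal_cdf(theta_hat, se, item.discrimination, tau[j - 1])
        up = logistic_normal_cdf(theta_hat, se, item.discrimination, tau[j])
        out = np.maximum(lo - up, floor)
        return float(out) if np.ndim(out) == 0 else out
    theta_hat = np.asarray(theta_hat, dtype=float)
    se_arr = np.asarray(se, dtype=float)
    cum = logistic_normal_cdf(
        theta_hat[..., None], se_arr[..., None], item.discrimination, tau
    )
    return np.maximum(-np.diff(cum, axis=-1), floor)


def tail_odds(z: float) -> float:
    """Expected one-in-N rarity of ``|score| > z`` under a unit normal.

    ``1 / (2 * (1 - Phi(z)))``.
    """
    if z <= 0:
        raise ValueError("z must be > 0")
    return float(1.0 / (2.0 * ndtr(-z)))
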
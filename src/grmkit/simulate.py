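"""Seeded generators for synthetic Likert-style studies.

Produces item banks with ordered thresholds, normal ability populations
(a unit-normal "calibration" group and a shifted "control" group by
default), and sparse ordinal response matrices, so the whole calibration /
scoring / evaluation pipeline is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grm import MISSING, ItemBank, ItemParameters, ResponseMatrix

__all__ = [
    "PopulationSpec",
    "BankSpec",
    "SimulatedStudy",
    "simulate_bank",
    "simulate_responses",
    "simulate_study",
]

#: Minimum gap enforced between adjacent thresholds of a simulated item.
MIN_THRESHOLD_GAP = 0.1


@dataclass(frozen=True)
class PopulationSpec:
    """A normal ability population to draw respondents from."""

    n_persons: int
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.ability_sd <= 0:
            raise ValueError("ability_sd must be > 0")


@dataclass(frozen=True)
class BankSpec:
    """Shape of a simulated item bank.

    ``n_categories`` may be a single integer or a per-item sequence.
    """

    n_items: int
    n_categories: int | tuple[int, ...] = 4
    discrimination_range: tuple[float, float] = (0.8, 2.5)
    threshold_spread: tuple[float, float] = (-2.5, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 2:
            raise ValueError("n_items must be >= 2")
        lo, hi = self.discrimination_range
        if not (0 < lo <= hi):
            raise ValueError("invalid discrimination_range")
        lo, hi = self.threshold_spread
        if lo >= hi:
            raise ValueError("invalid threshold_spread")

    def categories_per_item(self) -> np.ndarray:
        if isinstance(self.n_categories, int):
            cats = np.full(self.n_items, self.n_categories)
        else:
            cats = np.asarray(self.n_categories, dtype=int)
            if cats.shape != (self.n_items,):
                raise ValueError("per-item n_categories must have length n_items")
        if (cats < 2).any():
            raise ValueError("every item needs >= 2 categories")
        return cats


@dataclass(frozen=True)
class SimulatedStudy:
    """A bank plus claimant-like and control-like samples with truths."""

    bank: ItemBank
    claimant: ResponseMatrix
    claimant_theta: np.ndarray
    control: ResponseMatrix
    control_theta: np.ndarray
    seed: int


def simulate_bank(spec: BankSpec) -> ItemBank:
    """Draw an item bank: uniform discriminations, sorted spread-out thresholds.

    Thresholds are redrawn until adjacent gaps are all >= 0.1 (rejection),
    which is infeasible when the requested category count cannot fit in the
    spread.
    """
    cats = spec.categories_per_item()
    lo, hi = spec.threshold_spread
    if (cats.max() - 2) * MIN_THRESHOLD_GAP >= hi - lo:
        raise ValueError(
            f"threshold spread {spec.threshold_spread} cannot fit "
            f"{cats.max() - 1} thresholds with gap {MIN_THRESHOLD_GAP}"
        )
    rng = np.random.default_rng(spec.seed)
    a, b = spec.discrimination_range
    lam = rng.uniform(a, b, size=spec.n_items)
    items = []
    for i in range(spec.n_items):
        k = cats[i] - 1
        for _ in range(10_000):
            thr = np.sort(rng.uniform(lo, hi, size=k))
            if k == 1 or np.diff(thr).min() >= MIN_THRESHOLD_GAP:
                break
        else:  # pragma: no cover - rejection virtually never exhausts
            raise RuntimeError("could not draw ordered thresholds")
        items.append(
            ItemParameters(
                item_id=f"item{i + 1:03d}",
                n_categories=int(cats[i]),
                discrimination=float(lam[i]),
                thresholds=tuple(thr),
            )
        )
    return ItemBank(domain="synthetic", items=tuple(items))


def simulate_responses(
    bank: ItemBank,
    abilities: np.ndarray,
    missing_rate: float = 0.0,
    seed: int = 0,
    *,
    person_prefix: str = "p",
) -> ResponseMatrix:
    """Draw a response matrix from the GRM at the given abilities.

    Each response is drawn categorically from the item's category
    probabilities; a missing-at-random mask is applied at ``missing_rate``.
    Persons left with zero observed items get one randomly chosen response
    restored so the matrix invariant holds.
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    theta = np.asarray(abilities, dtype=float)
    rng = np.random.default_rng(seed)
    P, I = theta.size, len(bank)
    resp = np.empty((P, I), dtype=np.int64)
    lam, tau, ncat = bank.arrays()
    u = rng.random((P, I))
    for i, item in enumerate(bank.items):
        # cumulative Pr(X >= j) is decreasing in j; X = #{j >= 2 : u < Pr(X>=j)} + 1
        cum = 1.0 / (1.0 + np.exp(lam[i] * (tau[i, 1 : ncat[i]] - theta[:, None])))
        resp[:, i] = 1 + (u[:, i : i + 1] < cum).sum(axis=1)
    if missing_rate > 0:
        mask = rng.random((P, I)) < missing_rate
        keep = rng.integers(0, I, size=P)
        mask[np.arange(P), keep] = np.where(
            mask.all(axis=1), False, mask[np.arange(P), keep]
        )
        resp[mask] = MISSING
    return ResponseMatrix(
        person_ids=tuple(f"{person_prefix}{k + 1:05d}" for k in range(P)),
        item_ids=tuple(bank.item_ids),
        responses=resp,
    )


def simulate_study(
    bank_spec: BankSpec,
    claimant_spec: PopulationSpec | None = None,
    control_spec: PopulationSpec | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate a full two-population study from one bank.

    Defaults: claimants ~ N(0, 1) (the identifiability convention) with 500
    persons; controls ~ N(+0.5, 1) with 200 persons.  Person ids of the two
    samples are disjoint.
    """
    if claimant_spec is None:
        claimant_spec = PopulationSpec(500, 0.0, 1.0, label="claimant")
    if control_spec is None:
        control_spec = PopulationSpec(200, 0.5, 1.0, label="control")
    rng = np.random.default_rng(seed)
    bank = simulate_bank(bank_spec)
    th_claim = rng.normal(
        claimant_spec.ability_mean, claimant_spec.ability_sd, claimant_spec.n_persons
    )
    th_ctrl = rng.normal(
        control_spec.ability_mean, control_spec.ability_sd, control_spec.n_persons
    )
    claimant = simulate_responses(
        bank,
        th_claim,
        missing_rate,
        seed=rng.integers(2**31),
        person_prefix="claim",
    )
    control = simulate_responses(
        bank,
        th_ctrl,
        missing_rate,
        seed=rng.integers(2**31),
        person_prefix="ctrl",
    )
    return SimulatedStudy(
        bank=bank,
        claimant=claimant,
        claimant_theta=th_claim,
        control=control,
        control_theta=th_ctrl,
        seed=seed,
    )
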
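"""Synthetic Q-sorts: uniform random, or driven by a latent defensive profile.

The simulator makes every downstream module testable without clinical data.
A subject is a latent weight vector over the 30 defenses (the share of
defensive mass the instrument should attribute to each defense).  A rater
perceives each item's salience as the weight of its defense plus Gaussian
perturbation, then files items into the forced distribution from the top
rank down in order of perceived salience.  With zero noise the sort is a
deterministic function of the profile; as noise grows the sorts converge
to uniform random sorts.

All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .item_bank import DEFENSE_IDS, ItemBank, load_item_bank
from .qsort import DEFAULT_DISTRIBUTION, ForcedDistribution, QSort

__all__ = [
    "LatentProfile",
    "RaterModel",
    "RaterPanel",
    "random_sort",
    "profile_sort",
    "rater_panel",
    "random_profiles",
]


@dataclass(frozen=True)
class LatentProfile:
    """Target share of defensive mass per defense; sums to 1."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.weights) != set(DEFENSE_IDS):
            raise ValueError("profile must weight exactly D1..D30")
        vals = np.array([self.weights[d] for d in DEFENSE_IDS], float)
        if (vals < 0).any():
            raise ValueError("profile weights must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile weights must sum to 1, got {vals.sum()}")

    @classmethod
    def uniform(cls) -> "LatentProfile":
        return cls(weights={d: 1.0 / 30.0 for d in DEFENSE_IDS})

    @classmethod
    def from_weights(cls, weights: Mapping[str, float]) -> "LatentProfile":
        """Normalize arbitrary nonnegative weights (missing defenses get 0)."""
        raw = {d: float(weights.get(d, 0.0)) for d in DEFENSE_IDS}
        total = sum(raw.values())
        if total <= 0:
            raise ValueError("weights must have positive total")
        return cls(weights={d: w / total for d, w in raw.items()})

    @classmethod
    def concentrated(cls, defense_id: str, share: float = 1.0,
                     ) -> "LatentProfile":
        """All (or *share* of the) mass on one defense, rest uniform."""
        if defense_id not in DEFENSE_IDS:
            raise ValueError(f"unknown defense {defense_id!r}")
        rest = (1.0 - share) / 29.0
        return cls(weights={d: share if d == defense_id else rest
                            for d in DEFENSE_IDS})

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[d] for d in DEFENSE_IDS], float)


@dataclass(frozen=True)
class RaterModel:
    """Gaussian perturbation of item salience; noise_sd=0 is a perfect rater.

    noise_sd is on the same scale as the profile weights (which average
    1/30 ≈ 0.033 over the 30 defenses).
    """

    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _fill_by_salience(order: Sequence[int],
                      dist: ForcedDistribution,
                      meta: Optional[dict[str, str]] = None) -> QSort:
    """Assign items (most salient first) into ranks top-down by capacity."""
    assignment: dict[int, int] = {}
    idx = 0
    for rank in sorted(dist.ranks, reverse=True):
        for _ in range(dist.capacities[rank]):
            assignment[order[idx]] = rank
            idx += 1
    return QSort(assignment=assignment, meta=dict(meta or {}))


def random_sort(seed: int,
                dist: ForcedDistribution = DEFAULT_DISTRIBUTION) -> QSort:
    """A uniformly random valid sort (seeded permutation into rank slots)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.arange(1, dist.n_items + 1))
    return _fill_by_salience([int(i) for i in order], dist,
                             meta={"generator": "random_sort",
                                   "seed": str(seed)})


def profile_sort(profile: LatentProfile, rater: RaterModel,
                 dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                 bank: Optional[ItemBank] = None,
                 rng: Optional[np.random.Generator] = None) -> QSort:
    """A valid sort tracking *profile* with rater noise.

    Item i's salience is weight(defense(i)) + N(0, noise_sd); items are
    ranked by descending salience with ties broken by ascending item id
    (so noise_sd=0 is fully deterministic), then filled into ranks from
    the top down.  Pass *rng* to continue an existing stream (panels);
    otherwise the rater's seed starts a fresh one.
    """
    if bank is None:
        bank = _default_bank()
    if rng is None:
        rng = np.random.default_rng(rater.seed)
    n = dist.n_items
    base = np.array([profile.weights[bank.items[i].defense_id]
                     for i in range(1, n + 1)])
    eps = rng.normal(0.0, rater.noise_sd, size=n) if rater.noise_sd > 0 \
        else np.zeros(n)
    salience = base + eps
    # argsort ascending on (-salience, item_id) = descending salience,
    # ascending id on ties; lexsort's last key is primary.
    item_ids = np.arange(1, n + 1)
    order = item_ids[np.lexsort((item_ids, -salience))]
    return _fill_by_salience([int(i) for i in order], dist,
                             meta={"generator": "profile_sort",
                                   "noise_sd": str(rater.noise_sd),
                                   "seed": str(rater.seed)})


_BANK_CACHE: list[ItemBank] = []


def _default_bank() -> ItemBank:
    if not _BANK_CACHE:
        _BANK_CACHE.append(load_item_bank())
    return _BANK_CACHE[0]


@dataclass
class RaterPanel:
    """Sorts indexed subject x rater, plus the generating configuration."""

    sorts: dict[tuple[int, int], QSort]
    n_subjects: int
    n_raters: int
    profiles: tuple[LatentProfile, ...] = field(repr=False, default=())
    raters: tuple[RaterModel, ...] = field(repr=False, default=())

    def sort_for(self, subject: int, rater: int) -> QSort:
        return self.sorts[(subject, rater)]


def rater_panel(profiles: Sequence[LatentProfile],
                raters: Sequence[RaterModel],
                dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                bank: Optional[ItemBank] = None) -> RaterPanel:
    """One valid sort per (subject, rater) pair, reproducible from seeds.

    Each cell uses an independent generator seeded by (rater seed,
    subject index), so identical rater models produce identical sorts for
    every subject, and panels are insensitive to evaluation order.
    """
    if not profiles or not raters:
        raise ValueError("profiles and raters must be non-empty")
    if bank is None:
        bank = _default_bank()
    sorts: dict[tuple[int, int], QSort] = {}
    for s, profile in enumerate(profiles):
        for r, rater in enumerate(raters):
            rng = np.random.default_rng([rater.seed, s])
            qs = profile_sort(profile, rater, dist=dist, bank=bank, rng=rng)
            qs.meta.update({"subject": str(s), "rater": str(r)})
            sorts[(s, r)] = qs
    return RaterPanel(sorts=sorts, n_subjects=len(profiles),
                      n_raters=len(raters), profiles=tuple(profiles),
                      raters=tuple(raters))


def random_profiles(n: int, seed: int, alpha: float = 1.0,
                    ) -> list[LatentProfile]:
    """Subject profiles drawn from a symmetric Dirichlet(alpha) over the
    30 defenses — heterogeneous subjects with weight scale ~1/30."""
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet([alpha] * len(DEFENSE_IDS), size=n)
    return [LatentProfile(weights=dict(zip(DEFENSE_IDS, map(float, row))))
            for row in draws]
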
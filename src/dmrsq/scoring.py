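"""Quantitative scoring of a valid Q-sort.

All quantitative scores are ipsative percentages of the subject's total
defensive mass:

* 30 individual defense scores
      D = (sum of the ranks of the defense's five items - 5) * 100 / 234
  where 234 is the total rank mass of a valid sort (384) minus one unit
  per item, so the 30 scores always sum to exactly 100.
* 7 level scores (plus the hysterical / other-neurotic split of the
  neurotic level), each the sum of its member defense scores.
* 3 category scores (mature / neurotic / immature, plus the depressive /
  other-immature split of the immature category).
* the Overall Defensive Functioning index
      ODF = sum_L (L / 100) * level_number(L)
  a weighted mean of defensive mass on the 1-7 adaptiveness scale.

For non-default forced distributions the analogous normalizer (total rank
mass minus item count) is recomputed and a warning is issued, since only
the packaged distribution carries published scoring semantics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .item_bank import (
    CATEGORY_DEFENSES,
    DEFENSE_IDS,
    ItemBank,
    LEVEL_DEFENSES,
    LEVEL_NUMBER,
    SUBCATEGORY_DEFENSES,
    SUBLEVEL_DEFENSES,
)
from .qsort import (
    DEFAULT_DISTRIBUTION,
    ForcedDistribution,
    QSort,
    ValidationReport,
    validate_sort,
)

__all__ = [
    "DefenseScores",
    "LevelScores",
    "CategoryScores",
    "ODFScore",
    "DefensiveProfile",
    "InvalidSortError",
    "score_defenses",
    "score_levels",
    "score_categories",
    "compute_odf",
    "odf_from_items",
    "full_profile",
    "SCALE_NAMES",
]

_TOL = 1e-9

#: Every scale a profile exposes, in report order.
SCALE_NAMES: tuple[str, ...] = (
    DEFENSE_IDS
    + ("L1", "L2", "L3", "L4", "L5", "L5a", "L5b", "L6", "L7")
    + ("C1", "C1a", "C1b", "C2", "C3")
    + ("ODF",)
)


class InvalidSortError(Exception):
    """Scoring was refused because the sort fails validation."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(
            "sort fails forced-distribution validation: "
            + "; ".join(report.violations)
        )


@dataclass(frozen=True)
class DefenseScores:
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.scores) != set(DEFENSE_IDS):
            raise ValueError("defense scores must cover exactly D1..D30")
        if any(v < -_TOL for v in self.scores.values()):
            raise ValueError("defense scores must be nonnegative")
        total = sum(self.scores.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"defense scores must sum to 100, got {total}")

    def __getitem__(self, key: str) -> float:
        return self.scores[key]


@dataclass(frozen=True)
class LevelScores:
    scores: Mapping[str, float]  # L1..L7 plus L5a, L5b

    def __getitem__(self, key: str) -> float:
        return self.scores[key]


@dataclass(frozen=True)
class CategoryScores:
    scores: Mapping[str, float]  # C1, C2, C3 plus C1a, C1b

    def __getitem__(self, key: str) -> float:
        return self.scores[key]


@dataclass(frozen=True)
class ODFScore:
    """Overall Defensive Functioning on the 1-7 adaptiveness scale."""

    value: float

    def __post_init__(self) -> None:
        if not (1.0 - _TOL <= self.value <= 7.0 + _TOL):
            raise ValueError(f"ODF must lie in [1, 7], got {self.value}")

    @property
    def below_4(self) -> bool:
        """Advisory flag: ODF < 4 accompanies severe depression or
        personality pathology in the instrument's interpretive guidance."""
        return self.value < 4.0


@dataclass(frozen=True)
class DefensiveProfile:
    defense_scores: DefenseScores
    level_scores: LevelScores
    category_scores: CategoryScores
    odf: ODFScore
    meta: Mapping[str, str] = field(default_factory=dict)

    def get_scale(self, name: str) -> float:
        """Value of any named scale (D1..D30, L*, C*, or ODF)."""
        if name == "ODF":
            return self.odf.value
        if name in DEFENSE_IDS:
            return self.defense_scores[name]
        if name in self.level_scores.scores:
            return self.level_scores[name]
        if name in self.category_scores.scores:
            return self.category_scores[name]
        raise KeyError(f"unknown scale {name!r}")

    def to_dict(self) -> dict:
        return {
            "meta": dict(self.meta),
            "defenses": {d: self.defense_scores[d] for d in DEFENSE_IDS},
            "levels": dict(self.level_scores.scores),
            "categories": dict(self.category_scores.scores),
            "odf": self.odf.value,
            "odf_below_4": self.odf.below_4,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _check_default(dist: ForcedDistribution) -> None:
    if dist.capacities != DEFAULT_DISTRIBUTION.capacities:
        warnings.warn(
            "scoring a non-default forced distribution: proportional "
            "scores are computed with the analogous normalizer "
            f"({dist.normalizer}) but have no published interpretation",
            stacklevel=3,
        )


def score_defenses(sort: QSort, bank: ItemBank,
                   dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                   ) -> DefenseScores:
    """Proportional score of each defense from its five item ranks."""
    report = validate_sort(sort, dist)
    if not report.ok:
        raise InvalidSortError(report)
    _check_default(dist)
    norm = dist.normalizer
    scores = {}
    for d in DEFENSE_IDS:
        items = bank.items_for_defense(d)
        rank_sum = sum(sort.assignment[i] for i in items)
        scores[d] = (rank_sum - len(items)) * 100.0 / norm
    return DefenseScores(scores=scores)


def score_levels(d: DefenseScores) -> LevelScores:
    """Aggregate defense scores into the seven levels plus the L5 split."""
    scores = {lvl: sum(d[x] for x in members)
              for lvl, members in LEVEL_DEFENSES.items()}
    for sub, members in SUBLEVEL_DEFENSES.items():
        scores[sub] = sum(d[x] for x in members)
    return LevelScores(scores=scores)


def score_categories(d: DefenseScores) -> CategoryScores:
    """Aggregate defense scores into the tripartite categories."""
    scores = {cat: sum(d[x] for x in members)
              for cat, members in CATEGORY_DEFENSES.items()}
    for sub, members in SUBCATEGORY_DEFENSES.items():
        scores[sub] = sum(d[x] for x in members)
    return CategoryScores(scores=scores)


def compute_odf(l: LevelScores) -> ODFScore:
    """Level-weighted mean of defensive mass on the 1-7 scale."""
    value = sum(l[lvl] / 100.0 * n for lvl, n in LEVEL_NUMBER.items())
    return ODFScore(value=value)


def odf_from_items(sort: QSort, bank: ItemBank,
                   dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                   ) -> float:
    """ODF by direct item-level accumulation.

    Algebraically identical to :func:`compute_odf` composed with the
    level aggregation:  ODF = (sum_i level(i)*rank(i) - 675) / 234 for the
    default instrument, where 675 is one unit of rank per item weighted by
    its level.  Kept as a separate accumulation path so the identity can
    be checked.
    """
    report = validate_sort(sort, dist)
    if not report.ok:
        raise InvalidSortError(report)
    levels = np.array([bank.level_of_item(i)
                       for i in range(1, dist.n_items + 1)])
    ranks = np.array([sort.assignment[i]
                      for i in range(1, dist.n_items + 1)])
    min_mass = int(levels.sum())  # every item at rank 1
    return float((levels @ ranks - min_mass) / dist.normalizer)


def full_profile(sort: QSort, bank: ItemBank,
                 dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                 ) -> DefensiveProfile:
    """Defense, level, category and ODF scores for a valid sort."""
    d = score_defenses(sort, bank, dist)
    lvl = score_levels(d)
    cat = score_categories(d)
    odf = compute_odf(lvl)
    return DefensiveProfile(
        defense_scores=d, level_scores=lvl, category_scores=cat,
        odf=odf, meta=dict(sort.meta),
    )
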
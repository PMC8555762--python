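"""Forced-distribution Q-sorts.

A completed DMRS-Q rating assigns each of the 150 items to one of seven
ordinal ranks; the number of items per rank is fixed by the instrument's
forced distribution (rank 1, 60 items = "not used at all" ... rank 7,
6 items = "almost always used").  Scores are therefore ipsative: the total
rank mass of every valid sort is the same constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

__all__ = [
    "ForcedDistribution",
    "DEFAULT_DISTRIBUTION",
    "QSort",
    "ValidationReport",
    "SortFormatError",
    "validate_sort",
    "rank_histogram",
    "from_rank_vector",
    "to_rank_vector",
    "read_sort",
    "write_sort",
]


class SortFormatError(Exception):
    """A sort file or rank vector is structurally malformed."""


@dataclass(frozen=True)
class ForcedDistribution:
    """Rank capacities: how many items each rank must receive.

    Ranks must be consecutive integers starting at 1, with capacities
    strictly decreasing from rank 2 upward (higher ranks are scarcer).
    """

    capacities: Mapping[int, int]

    def __post_init__(self) -> None:
        caps = dict(self.capacities)
        ranks = sorted(caps)
        if not ranks or ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(
                f"ranks must be consecutive integers from 1; got {ranks}"
            )
        if any(caps[r] <= 0 for r in ranks):
            raise ValueError("all capacities must be positive")
        for r in ranks[1:-1]:
            if caps[r + 1] >= caps[r]:
                raise ValueError(
                    "capacities must strictly decrease above rank 1: "
                    f"cap({r + 1})={caps[r + 1]} >= cap({r})={caps[r]}"
                )
        object.__setattr__(self, "capacities", dict(caps))

    @property
    def ranks(self) -> tuple[int, ...]:
        return tuple(sorted(self.capacities))

    @property
    def n_items(self) -> int:
        return sum(self.capacities.values())

    @property
    def total_rank_mass(self) -> int:
        """Sum of rank(i) over a valid sort — constant by construction."""
        return sum(r * c for r, c in self.capacities.items())

    @property
    def normalizer(self) -> int:
        """Denominator of the proportional scoring formulas.

        Total rank mass minus one unit per item (the attainable minimum,
        all items at rank 1): 384 - 150 = 234 for the default instrument.
        """
        return self.total_rank_mass - self.n_items


#: The published DMRS-Q distribution.
DEFAULT_DISTRIBUTION = ForcedDistribution(
    {1: 60, 2: 30, 3: 20, 4: 16, 5: 10, 6: 8, 7: 6}
)


@dataclass
class QSort:
    """An item -> rank assignment plus free-text metadata.

    Construction does not assert validity; use :func:`validate_sort`.
    """

    assignment: dict[int, int]
    meta: dict[str, str] = field(default_factory=dict)

    def rank_of(self, item_id: int) -> int:
        return self.assignment[item_id]

    def items_at_rank(self, rank: int) -> tuple[int, ...]:
        return tuple(sorted(i for i, r in self.assignment.items()
                            if r == rank))


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.ok


def validate_sort(sort: QSort,
                  dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                  ) -> ValidationReport:
    """Check totality and per-rank capacities; violations are data."""
    violations: list[str] = []
    expected = set(range(1, dist.n_items + 1))
    present = set(sort.assignment)
    missing = expected - present
    extra = present - expected
    if missing:
        violations.append(f"unassigned: {sorted(missing)}")
    if extra:
        violations.append(f"unknown item ids: {sorted(extra)}")
    valid_ranks = set(dist.ranks)
    bad_rank = {i: r for i, r in sort.assignment.items()
                if r not in valid_ranks}
    if bad_rank:
        violations.append(f"out-of-range ranks: {bad_rank}")
    counts = rank_histogram(sort)
    for r in dist.ranks:
        n = counts.get(r, 0)
        cap = dist.capacities[r]
        if n != cap:
            violations.append(f"rank {r}: {n}/{cap}")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def rank_histogram(sort: QSort) -> dict[int, int]:
    """Count of items per rank (ranks with zero items omitted)."""
    counts: dict[int, int] = {}
    for r in sort.assignment.values():
        counts[r] = counts.get(r, 0) + 1
    return counts


def from_rank_vector(ranks: Sequence[int],
                     meta: Optional[dict[str, str]] = None,
                     dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                     ) -> QSort:
    """Build a QSort from a vector where entry i is the rank of item i+1.

    Only the format is checked (length, rank range); capacity validity is
    the caller's concern via :func:`validate_sort`.
    """
    ranks = list(ranks)
    if len(ranks) != dist.n_items:
        raise SortFormatError(
            f"expected {dist.n_items} ranks, got {len(ranks)}"
        )
    valid = set(dist.ranks)
    for i, r in enumerate(ranks, start=1):
        if not isinstance(r, (int,)) or isinstance(r, bool) or r not in valid:
            raise SortFormatError(f"item {i}: rank {r!r} not in {sorted(valid)}")
    return QSort(assignment={i: r for i, r in enumerate(ranks, start=1)},
                 meta=dict(meta or {}))


def to_rank_vector(sort: QSort,
                   dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                   ) -> list[int]:
    """Inverse of :func:`from_rank_vector` (requires a total assignment)."""
    try:
        return [sort.assignment[i] for i in range(1, dist.n_items + 1)]
    except KeyError as exc:
        raise SortFormatError(f"sort is not total: missing item {exc}") from exc


# --------------------------------------------------------------------------
# File round-trip: delimited (item_id,rank) or structured {meta, ranks}.
# --------------------------------------------------------------------------

def read_sort(path: str | Path) -> QSort:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SortFormatError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(doc, dict) or "ranks" not in doc:
            raise SortFormatError(f"{path}: expected object with 'ranks'")
        ranks = doc["ranks"]
        if (not isinstance(ranks, list)
                or not all(isinstance(r, int) for r in ranks)):
            raise SortFormatError(f"{path}: 'ranks' must be a list of integers")
        meta = {str(k): str(v) for k, v in (doc.get("meta") or {}).items()}
        return from_rank_vector(ranks, meta=meta)
    assignment: dict[int, int] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise SortFormatError(f"{path}: empty sort file")
    start = 1 if lines[0].lower().replace(" ", "").startswith("item_id") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise SortFormatError(
                f"{path}:{lineno}: expected 'item_id,rank', got {line!r}"
            )
        try:
            item_id, rank = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise SortFormatError(f"{path}:{lineno}: {exc}") from exc
        if item_id in assignment:
            raise SortFormatError(f"{path}:{lineno}: duplicate item {item_id}")
        assignment[item_id] = rank
    return QSort(assignment=assignment)


def write_sort(sort: QSort, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {"meta": sort.meta, "ranks": to_rank_vector(sort)}
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return
    lines = ["item_id,rank"]
    lines += [f"{i},{sort.assignment[i]}" for i in sorted(sort.assignment)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
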
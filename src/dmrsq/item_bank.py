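"""Item bank and defense hierarchy for the DMRS-Q instrument.

The DMRS-Q rates an individual's defensive functioning by sorting 150
observer-rated item statements — five per defense mechanism — into a forced
distribution.  This module is the single source of truth for the instrument:
the 30 defense mechanisms, their organization into seven adaptiveness levels
and three summary categories, and the 150 item statements with their
defense membership.

The hierarchy (most to least adaptive):

* L7 high adaptive  -> category C3 (mature)
* L6 obsessional, L5 neurotic -> category C2 (neurotic);
  L5 splits into L5a hysterical (dissociation, repression) and
  L5b other neurotic (displacement, reaction formation)
* L4 minor image-distorting, L3 disavowal, L2 major image-distorting,
  L1 action -> category C1 (immature); C1 splits into C1a depressive and
  C1b other-immature subsets
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "DefenseDef",
    "ItemRecord",
    "ItemBank",
    "ItemBankError",
    "BankParseError",
    "BankIntegrityError",
    "load_item_bank",
    "save_item_bank",
    "defense_for_item",
    "items_for_defense",
    "DEFENSE_IDS",
    "LEVEL_IDS",
    "LEVEL_DEFENSES",
    "SUBLEVEL_DEFENSES",
    "CATEGORY_LEVELS",
    "CATEGORY_DEFENSES",
    "SUBCATEGORY_DEFENSES",
    "LEVEL_NAMES",
    "CATEGORY_NAMES",
    "LEVEL_NUMBER",
    "LEVEL_DESCRIPTIONS",
]


class ItemBankError(Exception):
    """Base class for item-bank problems."""


class BankParseError(ItemBankError):
    """A bank file could not be parsed (malformed row, wrong columns...)."""


class BankIntegrityError(ItemBankError):
    """A parsed bank violates an instrument invariant."""


# --------------------------------------------------------------------------
# Hierarchy constants.  Defense numbering follows the instrument's scoring
# sheet: D1 (acting out, least adaptive) ... D30 (suppression, most adaptive).
# --------------------------------------------------------------------------

DEFENSE_IDS: tuple[str, ...] = tuple(f"D{i}" for i in range(1, 31))
LEVEL_IDS: tuple[str, ...] = tuple(f"L{i}" for i in range(1, 8))

LEVEL_DEFENSES: dict[str, tuple[str, ...]] = {
    "L1": ("D1", "D2", "D3"),
    "L2": ("D4", "D5", "D6"),
    "L3": ("D7", "D8", "D9", "D10"),
    "L4": ("D11", "D12", "D13", "D14", "D15"),
    "L5": ("D16", "D17", "D18", "D19"),
    "L6": ("D20", "D21", "D22"),
    "L7": ("D23", "D24", "D25", "D26", "D27", "D28", "D29", "D30"),
}

SUBLEVEL_DEFENSES: dict[str, tuple[str, ...]] = {
    "L5a": ("D18", "D19"),  # hysterical
    "L5b": ("D16", "D17"),  # other neurotic
}

CATEGORY_LEVELS: dict[str, tuple[str, ...]] = {
    "C1": ("L1", "L2", "L3", "L4"),  # immature
    "C2": ("L5", "L6"),              # neurotic
    "C3": ("L7",),                   # mature
}

CATEGORY_DEFENSES: dict[str, tuple[str, ...]] = {
    cat: tuple(d for lvl in levels for d in LEVEL_DEFENSES[lvl])
    for cat, levels in CATEGORY_LEVELS.items()
}

# Depressive vs non-depressive split of the immature category.
SUBCATEGORY_DEFENSES: dict[str, tuple[str, ...]] = {
    "C1a": ("D1", "D2", "D3", "D4", "D5", "D6", "D8", "D14", "D15"),
    "C1b": ("D7", "D9", "D10", "D11", "D12", "D13"),
}

LEVEL_NAMES: dict[str, str] = {
    "L1": "Action",
    "L2": "Major image-distorting",
    "L3": "Disavowal",
    "L4": "Minor image-distorting",
    "L5": "Neurotic",
    "L5a": "Hysterical",
    "L5b": "Other neurotic",
    "L6": "Obsessional",
    "L7": "High adaptive",
}

CATEGORY_NAMES: dict[str, str] = {
    "C1": "Immature",
    "C1a": "Depressive",
    "C1b": "Other immature",
    "C2": "Neurotic",
    "C3": "Mature",
}

#: Adaptiveness weight of each level on the 1-7 scale used by the ODF.
LEVEL_NUMBER: dict[str, int] = {f"L{i}": i for i in range(1, 8)}

#: Short functional summaries of what each level's defenses do (metadata
#: only; not used by any scoring formula).
LEVEL_DESCRIPTIONS: dict[str, str] = {
    "L7": "Most adaptive handling of stressors; conflict is perceived "
          "without distortion and dealt with directly (positive coping).",
    "L6": "Feelings are kept at a distance while the associated idea stays "
          "conscious (minimization, generalization, contradiction).",
    "L5": "The idea is kept out of awareness while its feelings find "
          "indirect, partial expression.",
    "L4": "Self-esteem is propped up by minor positive or negative "
          "distortions of the image of self or others.",
    "L3": "Unacceptable aspects of experience are disowned or "
          "misattributed, so no personal role in the problem is recognized.",
    "L2": "Self and others are kept in all-good / all-bad compartments; "
          "gross image distortion wards off intolerable anxiety.",
    "L1": "Distress is discharged through impulsive action, complaint, or "
          "covert opposition instead of reflection.",
}

_ITEMS_PER_DEFENSE = 5
_N_ITEMS = 150

_BANK_COLUMNS = [
    "item_id", "defense_id", "defense_name", "level_id", "level_name",
    "sublevel", "category_id", "subcategory", "flags", "text",
]


def _level_of_defense(defense_id: str) -> str:
    for lvl, members in LEVEL_DEFENSES.items():
        if defense_id in members:
            return lvl
    raise BankIntegrityError(f"defense {defense_id!r} belongs to no level")


def _sublevel_of_defense(defense_id: str) -> Optional[str]:
    for sub, members in SUBLEVEL_DEFENSES.items():
        if defense_id in members:
            return sub
    return None


def _category_of_level(level_id: str) -> str:
    for cat, levels in CATEGORY_LEVELS.items():
        if level_id in levels:
            return cat
    raise BankIntegrityError(f"level {level_id!r} belongs to no category")


def _subcategory_of_defense(defense_id: str) -> Optional[str]:
    for sub, members in SUBCATEGORY_DEFENSES.items():
        if defense_id in members:
            return sub
    return None


@dataclass(frozen=True)
class DefenseDef:
    """One of the 30 defense mechanisms with its place in the hierarchy."""

    defense_id: str
    name: str
    level_id: str
    sublevel: Optional[str]
    category_id: str
    subcategory: Optional[str]

    @property
    def level_number(self) -> int:
        return LEVEL_NUMBER[self.level_id]


@dataclass(frozen=True)
class ItemRecord:
    """A single item statement and its owning defense."""

    item_id: int
    defense_id: str
    text: str
    flags: tuple[str, ...] = ()


@dataclass
class ItemBank:
    """The full 150-item instrument, validated on construction."""

    items: dict[int, ItemRecord]
    defenses: dict[str, DefenseDef]
    version: str = "1.0"
    language: str = "en"
    _defense_items: dict[str, tuple[int, ...]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self._validate()
        by_defense: dict[str, list[int]] = {d: [] for d in DEFENSE_IDS}
        for rec in self.items.values():
            by_defense[rec.defense_id].append(rec.item_id)
        self._defense_items = {
            d: tuple(sorted(ids)) for d, ids in by_defense.items()
        }

    # -- integrity -----------------------------------------------------

    def _validate(self) -> None:
        if set(self.defenses) != set(DEFENSE_IDS):
            missing = set(DEFENSE_IDS) - set(self.defenses)
            extra = set(self.defenses) - set(DEFENSE_IDS)
            raise BankIntegrityError(
                f"expected defenses D1..D30; missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )
        for d in self.defenses.values():
            if d.level_id != _level_of_defense(d.defense_id):
                raise BankIntegrityError(
                    f"{d.defense_id}: declared level {d.level_id} does not "
                    f"match hierarchy ({_level_of_defense(d.defense_id)})"
                )
            if d.sublevel != _sublevel_of_defense(d.defense_id):
                raise BankIntegrityError(
                    f"{d.defense_id}: sublevel {d.sublevel!r} inconsistent"
                )
            if d.category_id != _category_of_level(d.level_id):
                raise BankIntegrityError(
                    f"{d.defense_id}: category {d.category_id!r} inconsistent"
                )
            if d.subcategory != _subcategory_of_defense(d.defense_id):
                raise BankIntegrityError(
                    f"{d.defense_id}: subcategory {d.subcategory!r} "
                    "inconsistent"
                )
        if set(self.items) != set(range(1, _N_ITEMS + 1)):
            missing = set(range(1, _N_ITEMS + 1)) - set(self.items)
            extra = set(self.items) - set(range(1, _N_ITEMS + 1))
            raise BankIntegrityError(
                f"expected items 1..150; missing={sorted(missing)} "
                f"extra={sorted(extra)}"
            )
        counts: dict[str, int] = {d: 0 for d in DEFENSE_IDS}
        for rec in self.items.values():
            if rec.defense_id not in counts:
                raise BankIntegrityError(
                    f"item {rec.item_id}: unknown defense {rec.defense_id!r}"
                )
            counts[rec.defense_id] += 1
        bad = {d: c for d, c in counts.items() if c != _ITEMS_PER_DEFENSE}
        if bad:
            raise BankIntegrityError(
                f"each defense must own exactly {_ITEMS_PER_DEFENSE} items; "
                f"violations: {bad}"
            )

    # -- queries -------------------------------------------------------

    def defense_for_item(self, item_id: int) -> DefenseDef:
        if item_id not in self.items:
            raise KeyError(f"item id {item_id} out of range 1..{_N_ITEMS}")
        return self.defenses[self.items[item_id].defense_id]

    def items_for_defense(self, defense_id: str) -> tuple[int, ...]:
        if defense_id not in self._defense_items:
            raise KeyError(f"unknown defense id {defense_id!r}")
        return self._defense_items[defense_id]

    def level_of_item(self, item_id: int) -> int:
        """Adaptiveness level (1-7) of the defense owning *item_id*."""
        return self.defense_for_item(item_id).level_number

    def text_of(self, item_id: int) -> str:
        if item_id not in self.items:
            raise KeyError(f"item id {item_id} out of range 1..{_N_ITEMS}")
        return self.items[item_id].text


# --------------------------------------------------------------------------
# Loading / saving
# --------------------------------------------------------------------------

def _bank_from_rows(rows: Iterable[Mapping[str, str]],
                    version: str = "1.0", language: str = "en") -> ItemBank:
    items: dict[int, ItemRecord] = {}
    seen_defenses: dict[str, DefenseDef] = {}
    for rownum, row in enumerate(rows, start=2):  # 1-based + header
        try:
            item_id = int(row["item_id"])
        except (KeyError, ValueError) as exc:
            raise BankParseError(f"row {rownum}: bad item_id: {exc}") from exc
        did = row.get("defense_id", "").strip()
        if not did:
            raise BankParseError(f"row {rownum}: missing defense_id")
        if item_id in items:
            raise BankIntegrityError(
                f"item {item_id} listed more than once "
                f"(row {rownum}; already under {items[item_id].defense_id})"
            )
        flags = tuple(f for f in row.get("flags", "").split(";") if f)
        items[item_id] = ItemRecord(
            item_id=item_id, defense_id=did,
            text=row.get("text", ""), flags=flags,
        )
        if did not in seen_defenses and did in DEFENSE_IDS:
            seen_defenses[did] = DefenseDef(
                defense_id=did,
                name=row.get("defense_name", did),
                level_id=row.get("level_id") or _level_of_defense(did),
                sublevel=(row.get("sublevel") or None),
                category_id=row.get("category_id")
                or _category_of_level(_level_of_defense(did)),
                subcategory=(row.get("subcategory") or None),
            )
    return ItemBank(items=items, defenses=seen_defenses,
                    version=version, language=language)


def load_item_bank(source: Optional[str | Path] = None) -> ItemBank:
    """Load and validate an item bank.

    With no *source*, the packaged English bank is used.  Delimited
    (``.csv``) and structured (``.json``) bank files are accepted.

    Raises
    ------
    BankParseError
        If the file cannot be parsed (the message names the row).
    BankIntegrityError
        If the parsed bank violates an instrument invariant (duplicate or
        missing items, wrong per-defense cardinality, hierarchy mismatch).
    """
    if source is None:
        ref = resources.files("dmrsq.data") / "dmrsq_items_en.csv"
        with ref.open("r", encoding="utf-8", newline="") as fh:
            return _bank_from_rows(csv.DictReader(fh))
    path = Path(source)
    if path.suffix.lower() == ".json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise BankParseError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(doc, dict) or "items" not in doc:
            raise BankParseError(f"{path}: expected object with 'items'")
        return _bank_from_rows(
            ({k: str(v) if v is not None else "" for k, v in row.items()}
             for row in doc["items"]),
            version=str(doc.get("version", "1.0")),
            language=str(doc.get("language", "en")),
        )
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "item_id" not in reader.fieldnames:
            raise BankParseError(f"{path}: missing header with item_id column")
        return _bank_from_rows(reader)


def _bank_rows(bank: ItemBank) -> list[dict[str, str]]:
    rows = []
    for item_id in sorted(bank.items):
        rec = bank.items[item_id]
        d = bank.defenses[rec.defense_id]
        rows.append({
            "item_id": str(item_id),
            "defense_id": d.defense_id,
            "defense_name": d.name,
            "level_id": d.level_id,
            "level_name": LEVEL_NAMES[d.level_id],
            "sublevel": d.sublevel or "",
            "category_id": d.category_id,
            "subcategory": d.subcategory or "",
            "flags": ";".join(rec.flags),
            "text": rec.text,
        })
    return rows


def save_item_bank(bank: ItemBank, path: str | Path) -> None:
    """Write *bank* as delimited (.csv) or structured (.json) text."""
    path = Path(path)
    rows = _bank_rows(bank)
    if path.suffix.lower() == ".json":
        doc = {"version": bank.version, "language": bank.language,
               "items": rows}
        path.write_text(json.dumps(doc, indent=1, ensure_ascii=False),
                        encoding="utf-8")
        return
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_BANK_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)


# Module-level convenience wrappers mirroring the bank methods.

def defense_for_item(bank: ItemBank, item_id: int) -> DefenseDef:
    return bank.defense_for_item(item_id)


def items_for_defense(bank: ItemBank, defense_id: str) -> tuple[int, ...]:
    return bank.items_for_defense(defense_id)
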
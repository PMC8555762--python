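"""Qualitative Defensive Profile Narrative and combined assessment report.

The DPN is the qualitative half of an assessment: the statements of all
items placed in the two highest ranks (6 and 7; 14 items under the default
distribution), each labelled with its defense and level.  The combined
report pairs the DPN with the quantitative profile derived from the same
sort, and renders deterministically as structured text (JSON), delimited
score tables (CSV), or markdown.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .item_bank import CATEGORY_NAMES, DEFENSE_IDS, ItemBank, LEVEL_NAMES
from .qsort import (
    DEFAULT_DISTRIBUTION,
    ForcedDistribution,
    QSort,
    validate_sort,
)
from .scoring import DefensiveProfile, InvalidSortError, full_profile

__all__ = [
    "DPNEntry",
    "DPNReport",
    "AssessmentReport",
    "build_dpn",
    "build_report",
    "render_report",
    "report_from_json",
    "REPORT_FORMATS",
]

REPORT_FORMATS = ("structured", "delimited", "markdown")

#: Ranks whose items enter the narrative (the two most descriptive piles).
DPN_RANKS = (7, 6)


@dataclass(frozen=True)
class DPNEntry:
    item_id: int
    rank: int
    statement: str
    defense_id: str
    defense_name: str
    level_name: str


@dataclass(frozen=True)
class DPNReport:
    entries: tuple[DPNEntry, ...]

    @property
    def narrative(self) -> str:
        """The entry statements concatenated as printed, in order."""
        return " ".join(e.statement for e in self.entries)


@dataclass(frozen=True)
class AssessmentReport:
    meta: Mapping[str, str]
    dpn: DPNReport
    profile: DefensiveProfile


def build_dpn(sort: QSort, bank: ItemBank,
              dist: ForcedDistribution = DEFAULT_DISTRIBUTION) -> DPNReport:
    """Narrative entries: rank 7 first, then rank 6, ascending item id.

    Rank 7 leads because those items are the "almost always used" pile.
    """
    report = validate_sort(sort, dist)
    if not report.ok:
        raise InvalidSortError(report)
    entries = []
    for rank in DPN_RANKS:
        for item_id in sort.items_at_rank(rank):
            d = bank.defense_for_item(item_id)
            entries.append(DPNEntry(
                item_id=item_id, rank=rank,
                statement=bank.text_of(item_id),
                defense_id=d.defense_id, defense_name=d.name,
                level_name=LEVEL_NAMES[d.level_id],
            ))
    return DPNReport(entries=tuple(entries))


def build_report(sort: QSort, bank: ItemBank,
                 dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                 ) -> AssessmentReport:
    """DPN plus quantitative profile, both from the same sort."""
    return AssessmentReport(
        meta=dict(sort.meta),
        dpn=build_dpn(sort, bank, dist),
        profile=full_profile(sort, bank, dist),
    )


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _scale_rows(profile: DefensiveProfile, bank: ItemBank) -> list[tuple]:
    """One (scale, label, value) row per reported scale: 30 defense rows,
    9 level rows, 5 category rows, and the ODF."""
    rows: list[tuple] = []
    for d in DEFENSE_IDS:
        rows.append((d, bank.defenses[d].name, profile.defense_scores[d]))
    for lvl in ("L1", "L2", "L3", "L4", "L5", "L5a", "L5b", "L6", "L7"):
        rows.append((lvl, LEVEL_NAMES[lvl], profile.level_scores[lvl]))
    for cat in ("C1", "C1a", "C1b", "C2", "C3"):
        rows.append((cat, CATEGORY_NAMES[cat], profile.category_scores[cat]))
    rows.append(("ODF", "Overall defensive functioning", profile.odf.value))
    return rows


def _to_structured(report: AssessmentReport) -> str:
    doc = {
        "meta": dict(report.meta),
        "dpn": [
            {"item_id": e.item_id, "rank": e.rank, "statement": e.statement,
             "defense_id": e.defense_id, "defense_name": e.defense_name,
             "level_name": e.level_name}
            for e in report.dpn.entries
        ],
        "profile": report.profile.to_dict(),
    }
    return json.dumps(doc, indent=1, sort_keys=True, ensure_ascii=False)


def _to_delimited(report: AssessmentReport, bank: ItemBank) -> str:
    lines = ["scale,label,value"]
    for scale, label, value in _scale_rows(report.profile, bank):
        label = '"' + label.replace('"', '""') + '"'
        lines.append(f"{scale},{label},{value:.6f}")
    return "\n".join(lines) + "\n"


def _to_markdown(report: AssessmentReport, bank: ItemBank) -> str:
    p = report.profile
    out = ["# DMRS-Q assessment report", ""]
    if report.meta:
        for k in sorted(report.meta):
            out.append(f"- **{k}**: {report.meta[k]}")
        out.append("")
    out += ["## Defensive Profile Narrative", "", report.dpn.narrative, ""]
    out += ["## Narrative items", ""]
    out.append("| item | rank | defense | level |")
    out.append("|---|---|---|---|")
    for e in report.dpn.entries:
        out.append(f"| {e.item_id} | {e.rank} | {e.defense_name} "
                   f"| {e.level_name} |")
    out += ["", "## Quantitative scores", ""]
    out.append(f"Overall Defensive Functioning (1-7): **{p.odf.value:.2f}**"
               + ("  *(ODF < 4)*" if p.odf.below_4 else ""))
    out += ["", "| scale | label | % |", "|---|---|---|"]
    for scale, label, value in _scale_rows(p, bank)[:-1]:
        out.append(f"| {scale} | {label} | {value:.2f} |")
    out.append("")
    return "\n".join(out)


def render_report(report: AssessmentReport, format: str,
                  bank: ItemBank) -> str:
    """Deterministic serialization in one of ``REPORT_FORMATS``."""
    if format == "structured":
        return _to_structured(report)
    if format == "delimited":
        return _to_delimited(report, bank)
    if format == "markdown":
        return _to_markdown(report, bank)
    raise ValueError(
        f"unknown report format {format!r}; expected one of {REPORT_FORMATS}"
    )


def report_from_json(text: str) -> AssessmentReport:
    """Parse the structured rendering back into an AssessmentReport."""
    from .scoring import (
        CategoryScores, DefenseScores, DefensiveProfile, LevelScores, ODFScore,
    )

    doc = json.loads(text)
    entries = tuple(
        DPNEntry(item_id=e["item_id"], rank=e["rank"],
                 statement=e["statement"], defense_id=e["defense_id"],
                 defense_name=e["defense_name"], level_name=e["level_name"])
        for e in doc["dpn"]
    )
    prof = doc["profile"]
    profile = DefensiveProfile(
        defense_scores=DefenseScores(scores=prof["defenses"]),
        level_scores=LevelScores(scores=prof["levels"]),
        category_scores=CategoryScores(scores=prof["categories"]),
        odf=ODFScore(value=prof["odf"]),
        meta=prof.get("meta", {}),
    )
    return AssessmentReport(meta=doc.get("meta", {}), dpn=DPNReport(entries),
                            profile=profile)
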
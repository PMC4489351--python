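"""Functional / lost / unknown verdicts from lesion reports.

The calling rule mirrors the screening criteria: the isoform is called
lost only when the promoter is rearranged or absent, the splice donor
is mutated or deleted, both start codons are mutated, an ORF-disrupting
lesion (frameshift or premature stop) sits in the coding block, or the
whole region is missing. Loss of a single start codon is tolerated:
the in vitro translation evidence shows the remaining ATG (notably
ATG2 alone, as in Equus and Vicugna) is a potent initiation site.
Kozak weakness alone never triggers loss. Low-coverage rows are called
unknown and excluded from downstream event counting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .features import (
    DonorStatus,
    LesionReport,
    LesionType,
    PromoterStatus,
)

_LOSS_LESIONS = frozenset(
    {
        LesionType.REGION_ABSENT,
        LesionType.DONOR_LOSS,
        LesionType.FRAMESHIFT_INDEL,
        LesionType.PREMATURE_STOP,
        LesionType.PROMOTER_DELETION,
        LesionType.PROMOTER_INSERTION,
    }
)


class State(str, enum.Enum):
    FUNCTIONAL = "functional"
    LOST = "lost"
    UNKNOWN = "unknown"


@dataclass
class FunctionalityCall:
    species_id: str
    state: State
    reasons: list[str]
    initiation_site: int | None  # 1, 2 or None


def call_functionality(report: LesionReport) -> FunctionalityCall:
    """Convert one lesion report into a functionality verdict."""
    if report.coverage_flag:
        return FunctionalityCall(report.species_id, State.UNKNOWN, ["low coverage"], None)

    reasons: list[str] = []
    if report.promoter_status is PromoterStatus.REARRANGED:
        reasons.append("promoter rearranged")
    elif report.promoter_status is PromoterStatus.ABSENT:
        reasons.append("promoter absent")
    if report.donor_status is DonorStatus.LOST:
        reasons.append("splice donor lost")

    s1, s2 = report.start_codons
    if not s1.intact and not s2.intact:
        if s1.ambiguous or s2.ambiguous:
            return FunctionalityCall(
                report.species_id, State.UNKNOWN, ["start codon state ambiguous"], None
            )
        reasons.append("both start codons mutated")

    for lesion in report.lesions:
        if lesion.type in (LesionType.FRAMESHIFT_INDEL, LesionType.PREMATURE_STOP):
            reasons.append(f"{lesion.type.value} at {lesion.start + 1}-{lesion.end}")
        elif lesion.type is LesionType.REGION_ABSENT:
            reasons.append("region absent")

    if reasons:
        return FunctionalityCall(report.species_id, State.LOST, reasons, None)
    if report.donor_status is DonorStatus.UNKNOWN:
        return FunctionalityCall(
            report.species_id, State.UNKNOWN, ["donor state ambiguous"], None
        )
    site = 1 if s1.intact else 2
    return FunctionalityCall(report.species_id, State.FUNCTIONAL, ["intact"], site)


def call_all(reports: list[LesionReport]) -> dict[str, FunctionalityCall]:
    """One verdict per species; duplicate species are an input error."""
    calls: dict[str, FunctionalityCall] = {}
    for report in reports:
        if report.species_id in calls:
            raise ValueError(f"duplicate species id: {report.species_id}")
        calls[report.species_id] = call_functionality(report)
    return calls


def character_map(calls: dict[str, FunctionalityCall]) -> dict[str, State]:
    """Species -> presence/absence character state."""
    return {sp: call.state for sp, call in calls.items()}


def state_counts(calls: dict[str, FunctionalityCall]) -> dict[str, int]:
    counts = {state.value: 0 for state in State}
    for call in calls.values():
        counts[call.state.value] += 1
    return counts


_SYMBOL = {State.FUNCTIONAL: "1", State.LOST: "0", State.UNKNOWN: "?"}


def presence_matrix(calls: dict[str, FunctionalityCall]) -> str:
    """Nexus-style one-character 0/1/? matrix (presence = 1)."""
    lines = ["#NEXUS", "BEGIN DATA;"]
    lines.append(f"  DIMENSIONS NTAX={len(calls)} NCHAR=1;")
    lines.append('  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS="01";')
    lines.append("  MATRIX")
    for sp in sorted(calls):
        lines.append(f"    {sp.replace(' ', '_')} {_SYMBOL[calls[sp].state]}")
    lines.append("  ;")
    lines.append("END;")
    return "\n".join(lines) + "\n"
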
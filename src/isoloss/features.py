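"""Lesion detection over aligned alternative-first-exon regions.

Each detector is a deterministic function of one species row, the
reference row and the shared :class:`FeatureAnnotation`. Detected
lesions are the functionality criteria used downstream: promoter
deletion/insertion (rearrangement), whole-region absence, splice-donor
loss, loss of either start codon, frameshift indels and premature stop
codons in the exon's coding portion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .annotation import GAP, FeatureAnnotation, RegionRow, ref_base_columns

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# thresholds for promoter assessment: the attested rearrangement is a
# 72 bp insertion, well above alignment noise, so indels >= 30 bp that
# hit the TSS block count as rearrangement; >= 90% gapping as absence.
MIN_PROMOTER_INDEL = 30
ABSENT_GAP_FRACTION = 0.90


class LesionType(str, enum.Enum):
    PROMOTER_DELETION = "promoter_deletion"
    PROMOTER_INSERTION = "promoter_insertion"
    REGION_ABSENT = "region_absent"
    DONOR_LOSS = "donor_loss"
    START1_LOSS = "start1_loss"
    START2_LOSS = "start2_loss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    PREMATURE_STOP = "premature_stop"


#: lesion types whose homology comparison also requires identical length
INDEL_TYPES = frozenset(
    {
        LesionType.PROMOTER_DELETION,
        LesionType.PROMOTER_INSERTION,
        LesionType.FRAMESHIFT_INDEL,
    }
)


class KozakClass(str, enum.Enum):
    STRONG = "strong"
    ADEQUATE = "adequate"
    WEAK = "weak"


class PromoterStatus(str, enum.Enum):
    INTACT = "intact"
    REARRANGED = "rearranged"
    ABSENT = "absent"


class DonorStatus(str, enum.Enum):
    INTACT = "intact"
    LOST = "lost"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Lesion:
    type: LesionType
    start: int  # alignment columns, 0-based half-open
    end: int
    length_bp: int
    detail: str = ""

    def overlaps(self, other: "Lesion") -> bool:
        return self.start < other.end and other.start < self.end


def lesions_homologous(a: Lesion, b: Lesion) -> bool:
    """Shared-ancestry proxy: same type, overlapping span, and for
    indels an identical ungapped length."""
    if a.type != b.type or not a.overlaps(b):
        return False
    if a.type in INDEL_TYPES and a.length_bp != b.length_bp:
        return False
    return True


@dataclass
class StartCodonStatus:
    which: int  # 1 or 2
    observed_codon: str
    intact: bool
    kozak_class: KozakClass | None = None
    ambiguous: bool = False  # codon contains N: status unknown, not lost


@dataclass
class LesionReport:
    species_id: str
    start_codons: tuple[StartCodonStatus, StartCodonStatus]
    lesions: list[Lesion]
    promoter_status: PromoterStatus
    donor_status: DonorStatus
    coverage_flag: bool = False


def classify_context(context: str, codon_index: int) -> KozakClass:
    """Score an initiation context given the codon's index in ``context``.

    Only the two dominant consensus positions are scored: -3 purine
    (A/G) and +4 G. Both -> strong, one -> adequate, neither -> weak.
    An N (or a truncated window) at a scored position counts as
    unsatisfied. Works for ATG and near-cognate codons alike.
    """
    context = context.upper().replace("U", "T")
    minus3 = context[codon_index - 3] if codon_index >= 3 else ""
    plus4 = context[codon_index + 3] if codon_index + 3 < len(context) else ""
    hits = (minus3 in "AG") + (plus4 == "G")
    return (KozakClass.WEAK, KozakClass.ADEQUATE, KozakClass.STRONG)[hits]


def score_kozak(context: str) -> KozakClass:
    """Classify the initiation context of an intact ATG.

    ``context`` is the gap-stripped window -6..+4 around the A of the
    ATG (10 nt when complete; may be truncated at a sequence edge).
    """
    context = context.upper().replace("U", "T")
    # a complete window puts the ATG at index 6; a window truncated at
    # either edge shifts it to len-4 (+4 retained) or len-3 (+4 lost)
    for idx in (6, len(context) - 4, len(context) - 3):
        if idx >= 0 and context[idx : idx + 3] == "ATG":
            atg_idx = idx
            break
    else:
        raise ValueError("no ATG found in Kozak window")
    return classify_context(context, atg_idx)


def _codon_columns(reference: str, pos: int) -> list[int]:
    """First three reference-base columns at/after ``pos``."""
    cols = []
    c = pos
    while len(cols) < 3 and c < len(reference):
        if reference[c] != GAP:
            cols.append(c)
        c += 1
    return cols


def _kozak_context(row: str, pos: int) -> str:
    """Gap-stripped -6..+4 window around the row base at column pos."""
    ungapped = []
    idx_at_pos = None
    for c, ch in enumerate(row):
        if ch != GAP:
            if c == pos:
                idx_at_pos = len(ungapped)
            ungapped.append(ch)
    if idx_at_pos is None:
        return ""
    return "".join(ungapped[max(0, idx_at_pos - 6) : idx_at_pos + 4])


def scan_start_codons(
    row: RegionRow, reference: RegionRow, ann: FeatureAnnotation
) -> tuple[StartCodonStatus, StartCodonStatus]:
    """Read both annotated start codons in this row.

    A codon is intact iff the three row bases at the annotated
    reference columns read exactly ATG; a gap at any of them is
    reported as '-' with intact False; an N makes the status ambiguous
    (unknown) rather than lost. Kozak class is scored only when intact.
    """
    out = []
    for which, pos in ((1, ann.atg1_pos), (2, ann.atg2_pos)):
        cols = _codon_columns(reference.columns, pos)
        codon = "".join(row.columns[c] for c in cols) if len(cols) == 3 else "-" * 3
        intact = codon == "ATG"
        ambiguous = (not intact) and ("N" in codon)
        kozak = score_kozak(_kozak_context(row.columns, pos)) if intact else None
        out.append(StartCodonStatus(which, codon, intact, kozak, ambiguous))
    return out[0], out[1]


def _indel_runs(row: str, ref: str, start: int, end: int):
    """Maximal deletion/insertion runs of ``row`` vs ``ref`` intersecting
    [start, end): yields (kind, run_start, run_end, length_bp) with the
    ungapped length counted inside the window only."""
    width = len(ref)
    c = 0
    while c < width:
        if row[c] == GAP and ref[c] != GAP:
            kind = "deletion"
        elif ref[c] == GAP and row[c] != GAP:
            kind = "insertion"
        else:
            c += 1
            continue
        run_start = c
        while c < width and (
            (kind == "deletion" and row[c] == GAP and ref[c] != GAP)
            or (kind == "insertion" and ref[c] == GAP and row[c] != GAP)
        ):
            c += 1
        run_end = c
        if run_start < end and start < run_end:
            lo, hi = max(run_start, start), min(run_end, end)
            strand = ref if kind == "deletion" else row
            length = sum(1 for i in range(lo, hi) if strand[i] != GAP)
            if length:
                yield kind, run_start, run_end, length


def detect_orf_disruptions(
    row: RegionRow, reference: RegionRow, ann: FeatureAnnotation
) -> list[Lesion]:
    """Frameshift indels and premature stops in the coding block.

    Frame is anchored at ATG1's annotated column regardless of ATG
    status; indels shift the downstream frame implicitly because codons
    are read off the row's consecutive ungapped bases. Every in-frame
    stop strictly before the donor is reported. A fully gapped coding
    block yields a single region_absent lesion instead.
    """
    cstart, cend = ann.coding_block
    coding_cols = [
        c for c in range(cstart, cend) if row.columns[c] != GAP
    ]
    if not coding_cols:
        lo, hi = ann.region_span()
        return [Lesion(LesionType.REGION_ABSENT, lo, hi, 0, "coding block absent")]

    lesions: list[Lesion] = []
    for kind, rs, re_, length in _indel_runs(row.columns, reference.columns, cstart, cend):
        if length % 3 != 0:
            lesions.append(
                Lesion(
                    LesionType.FRAMESHIFT_INDEL,
                    rs,
                    re_,
                    length,
                    f"{kind} of {length} bp",
                )
            )

    base_cols = [
        c for c in range(ann.atg1_pos, ann.donor_pos) if row.columns[c] != GAP
    ]
    seq = "".join(row.columns[c] for c in base_cols)
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            lesions.append(
                Lesion(
                    LesionType.PREMATURE_STOP,
                    base_cols[i],
                    base_cols[i + 2] + 1,
                    3,
                    f"in-frame {codon}",
                )
            )
    return lesions


def check_splice_donor(
    row: RegionRow, reference: RegionRow, ann: FeatureAnnotation
) -> DonorStatus:
    """Intact iff the two ungapped bases at the donor position read GT.

    Any other dinucleotide (including the GC variant) is treated as
    loss; gapped columns mean the donor was deleted; an N is unknown.
    """
    cols = _codon_columns(reference.columns, ann.donor_pos)[:2]
    dinuc = "".join(row.columns[c] for c in cols) if len(cols) == 2 else "--"
    if dinuc == "GT":
        return DonorStatus.INTACT
    if "N" in dinuc:
        return DonorStatus.UNKNOWN
    return DonorStatus.LOST


def assess_promoter(
    row: RegionRow, reference: RegionRow, ann: FeatureAnnotation
) -> tuple[PromoterStatus, list[Lesion]]:
    """Indel-based promoter verdict.

    absent: >= 90% of the promoter block's reference-base columns are
    gapped in this row. rearranged: a deletion >= 30 bp overlapping the
    TSS block, or an insertion >= 30 bp within it. Qualifying indels are
    emitted as lesions. Substitution-level divergence is not scored.
    """
    pcols = ref_base_columns(reference.columns, *ann.promoter_block)
    gapped = sum(1 for c in pcols if row.columns[c] == GAP)
    lesions: list[Lesion] = []
    status = PromoterStatus.INTACT
    if pcols and gapped / len(pcols) >= ABSENT_GAP_FRACTION:
        status = PromoterStatus.ABSENT
        lesions.append(
            Lesion(
                LesionType.PROMOTER_DELETION,
                ann.promoter_block[0],
                ann.promoter_block[1],
                gapped,
                "promoter block gapped",
            )
        )
    tstart, tend = ann.tss_block
    for kind, rs, re_, length in _indel_runs(row.columns, reference.columns, tstart, tend):
        if length < MIN_PROMOTER_INDEL:
            continue
        ltype = (
            LesionType.PROMOTER_DELETION
            if kind == "deletion"
            else LesionType.PROMOTER_INSERTION
        )
        lesions.append(Lesion(ltype, rs, re_, length, f"{kind} in TSS block"))
        if status is PromoterStatus.INTACT:
            status = PromoterStatus.REARRANGED
    return status, lesions


def build_feature_report(
    row: RegionRow, reference: RegionRow, ann: FeatureAnnotation
) -> LesionReport:
    """Aggregate all detectors into one deterministic report."""
    if len(row.columns) != len(reference.columns):
        raise ValueError(f"{row.species_id}: row length != reference length")

    region_cols = ref_base_columns(reference.columns, *ann.region_span())
    if region_cols and all(row.columns[c] == GAP for c in region_cols):
        lo, hi = ann.region_span()
        s1 = StartCodonStatus(1, "---", False)
        s2 = StartCodonStatus(2, "---", False)
        return LesionReport(
            species_id=row.species_id,
            start_codons=(s1, s2),
            lesions=[Lesion(LesionType.REGION_ABSENT, lo, hi, 0, "whole region absent")],
            promoter_status=PromoterStatus.ABSENT,
            donor_status=DonorStatus.LOST,
            coverage_flag=row.coverage_flag,
        )

    s1, s2 = scan_start_codons(row, reference, ann)
    lesions: list[Lesion] = []
    for status in (s1, s2):
        if not status.intact and not status.ambiguous:
            ltype = LesionType.START1_LOSS if status.which == 1 else LesionType.START2_LOSS
            pos = ann.atg1_pos if status.which == 1 else ann.atg2_pos
            lesions.append(
                Lesion(ltype, pos, pos + 3, 3, f"codon {status.observed_codon}")
            )

    promoter_status, promoter_lesions = assess_promoter(row, reference, ann)
    lesions.extend(promoter_lesions)

    orf_lesions = detect_orf_disruptions(row, reference, ann)
    lesions.extend(orf_lesions)

    donor_status = check_splice_donor(row, reference, ann)
    if donor_status is DonorStatus.LOST:
        cols = _codon_columns(reference.columns, ann.donor_pos)[:2]
        dinuc = "".join(row.columns[c] for c in cols) if len(cols) == 2 else "--"
        detail = "donor deleted" if "-" in dinuc else f"donor {dinuc}"
        lesions.append(
            Lesion(LesionType.DONOR_LOSS, ann.donor_pos, ann.donor_pos + 2, 2, detail)
        )

    lesions.sort(key=lambda l: (l.start, l.end, l.type.value))
    return LesionReport(
        species_id=row.species_id,
        start_codons=(s1, s2),
        lesions=lesions,
        promoter_status=promoter_status,
        donor_status=donor_status,
        coverage_flag=row.coverage_flag,
    )
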
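"""Feature annotation and aligned-region containers.

Coordinates are 0-based half-open alignment columns internally; all
human-readable output (TSV, CLI) uses 1-based inclusive coordinates.
Inputs are assumed pre-oriented to the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GAP = "-"
VALID_CHARS = frozenset("ACGTN-")


@dataclass(frozen=True)
class FeatureAnnotation:
    """Reference-alignment coordinates of the scored functional blocks.

    The region screened is an alternative first exon together with its
    putative promoter: a ~500-column promoter block, the conserved block
    where the transcription start maps (tss_block), two in-frame start
    codons (atg1, atg2), the coding portion of the exon, and the splice
    donor dinucleotide (first intronic base at donor_pos).
    """

    promoter_block: tuple[int, int]
    tss_block: tuple[int, int]
    atg1_pos: int
    atg2_pos: int
    coding_block: tuple[int, int]
    donor_pos: int

    def validate(self, width: int | None = None) -> None:
        p, t, c = self.promoter_block, self.tss_block, self.coding_block
        if not (p[0] < p[1] <= t[0] < t[1] <= self.atg1_pos):
            raise ValueError("blocks must be ordered promoter < tss <= atg1")
        if not (self.atg1_pos < self.atg2_pos < c[1] <= self.donor_pos):
            raise ValueError("atg1 < atg2 < coding end <= donor required")
        if not (c[0] <= self.atg1_pos):
            raise ValueError("atg1 must lie in the coding block")
        if width is not None and not (0 <= p[0] and self.donor_pos + 2 <= width):
            raise ValueError("annotation exceeds alignment width")

    def region_span(self) -> tuple[int, int]:
        """Full annotated region, promoter start through donor dinucleotide."""
        return (self.promoter_block[0], self.donor_pos + 2)


@dataclass
class RegionRow:
    """One species' gapped row over the annotated region."""

    species_id: str
    columns: str
    coverage_flag: bool = False

    def __post_init__(self) -> None:
        bad = set(self.columns.upper()) - VALID_CHARS
        if bad:
            raise ValueError(f"{self.species_id}: invalid characters {sorted(bad)}")
        self.columns = self.columns.upper()


@dataclass
class RegionAlignment:
    """Aligned orthologous rows sharing one annotation; reference first."""

    reference: RegionRow
    rows: list[RegionRow] = field(default_factory=list)
    annotation: FeatureAnnotation | None = None

    def __post_init__(self) -> None:
        width = len(self.reference.columns)
        for row in self.rows:
            if len(row.columns) != width:
                raise ValueError(f"{row.species_id}: row length != alignment width")
        if self.annotation is not None:
            self.annotation.validate(width)

    @property
    def width(self) -> int:
        return len(self.reference.columns)

    def all_rows(self) -> list[RegionRow]:
        return [self.reference, *self.rows]


def ref_base_columns(reference: str, start: int, end: int) -> list[int]:
    """Columns in [start, end) where the reference carries a base."""
    return [c for c in range(start, end) if reference[c] != GAP]


def ungapped_length(row: str, start: int, end: int) -> int:
    return sum(1 for c in range(start, end) if row[c] != GAP)
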
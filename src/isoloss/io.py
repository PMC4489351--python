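"""Readers and writers for the pipeline's plain-text dialects.

Alignments are FASTA (reference row first, gap character '-'); a row
whose FASTA description contains ``coverage=low`` is flagged as a
low-coverage assembly. Annotations are small YAML configs with 1-based
inclusive coordinates. Tabular artefacts (lesion reports, calls,
events, counts, expression calls) are TSV; human-readable coordinates
are 1-based inclusive throughout.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import FeatureAnnotation, RegionAlignment, RegionRow
from .calling import FunctionalityCall, State
from .features import (
    DonorStatus,
    KozakClass,
    Lesion,
    LesionReport,
    LesionType,
    PromoterStatus,
    StartCodonStatus,
)
from .phylo import LossEvent

LOW_COVERAGE_TOKEN = "coverage=low"


def read_alignment(path: str | Path, annotation: FeatureAnnotation | None = None) -> RegionAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 1:
        raise ValueError(f"no sequences in {path}")

    def to_row(rec) -> RegionRow:
        return RegionRow(
            species_id=rec.id,
            columns=str(rec.seq),
            coverage_flag=LOW_COVERAGE_TOKEN in rec.description,
        )

    return RegionAlignment(
        reference=to_row(records[0]),
        rows=[to_row(r) for r in records[1:]],
        annotation=annotation,
    )


def write_alignment(alignment: RegionAlignment, path: str | Path) -> None:
    records = []
    for row in alignment.all_rows():
        desc = LOW_COVERAGE_TOKEN if row.coverage_flag else ""
        records.append(SeqRecord(Seq(row.columns), id=row.species_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_annotation(path: str | Path) -> FeatureAnnotation:
    """YAML with 1-based inclusive intervals, e.g. ``tss_block: [501, 652]``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def block(key: str) -> tuple[int, int]:
        lo, hi = raw[key]
        return int(lo) - 1, int(hi)

    ann = FeatureAnnotation(
        promoter_block=block("promoter_block"),
        tss_block=block("tss_block"),
        atg1_pos=int(raw["atg1"]) - 1,
        atg2_pos=int(raw["atg2"]) - 1,
        coding_block=block("coding_block"),
        donor_pos=int(raw["donor"]) - 1,
    )
    ann.validate()
    return ann


def write_annotation(ann: FeatureAnnotation, path: str | Path) -> None:
    raw = {
        "promoter_block": [ann.promoter_block[0] + 1, ann.promoter_block[1]],
        "tss_block": [ann.tss_block[0] + 1, ann.tss_block[1]],
        "atg1": ann.atg1_pos + 1,
        "atg2": ann.atg2_pos + 1,
        "coding_block": [ann.coding_block[0] + 1, ann.coding_block[1]],
        "donor": ann.donor_pos + 1,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


_REPORT_COLUMNS = [
    "species", "feature", "status", "lesion_type", "start", "end", "length_bp", "detail",
]


def reports_to_frame(reports: list[LesionReport]) -> pd.DataFrame:
    """Flatten reports to TSV rows: one row per scored feature plus one
    per lesion; coordinates 1-based inclusive."""
    rows = []
    for rep in reports:
        for status in rep.start_codons:
            detail = status.observed_codon
            if status.kozak_class is not None:
                detail += f" kozak={status.kozak_class.value}"
            rows.append(
                {
                    "species": rep.species_id,
                    "feature": f"start_codon_{status.which}",
                    "status": "ambiguous"
                    if status.ambiguous
                    else ("intact" if status.intact else "lost"),
                    "lesion_type": "", "start": "", "end": "", "length_bp": "",
                    "detail": detail,
                }
            )
        rows.append(
            {
                "species": rep.species_id, "feature": "promoter",
                "status": rep.promoter_status.value,
                "lesion_type": "", "start": "", "end": "", "length_bp": "", "detail": "",
            }
        )
        rows.append(
            {
                "species": rep.species_id, "feature": "donor",
                "status": rep.donor_status.value,
                "lesion_type": "", "start": "", "end": "", "length_bp": "", "detail": "",
            }
        )
        rows.append(
            {
                "species": rep.species_id, "feature": "coverage",
                "status": "low" if rep.coverage_flag else "ok",
                "lesion_type": "", "start": "", "end": "", "length_bp": "", "detail": "",
            }
        )
        for lesion in rep.lesions:
            rows.append(
                {
                    "species": rep.species_id, "feature": "lesion", "status": "",
                    "lesion_type": lesion.type.value,
                    "start": lesion.start + 1, "end": lesion.end,
                    "length_bp": lesion.length_bp, "detail": lesion.detail,
                }
            )
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def write_reports(reports: list[LesionReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False)


def read_reports(path: str | Path) -> list[LesionReport]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    reports = []
    for species, grp in df.groupby("species", sort=False):
        starts: dict[int, StartCodonStatus] = {}
        promoter = PromoterStatus.INTACT
        donor = DonorStatus.INTACT
        coverage = False
        lesions: list[Lesion] = []
        for rec in grp.itertuples(index=False):
            if rec.feature.startswith("start_codon_"):
                which = int(rec.feature[-1])
                detail = rec.detail.split()
                codon = detail[0] if detail else "---"
                kozak = None
                for token in detail[1:]:
                    if token.startswith("kozak="):
                        kozak = KozakClass(token.split("=", 1)[1])
                starts[which] = StartCodonStatus(
                    which, codon, rec.status == "intact", kozak,
                    ambiguous=rec.status == "ambiguous",
                )
            elif rec.feature == "promoter":
                promoter = PromoterStatus(rec.status)
            elif rec.feature == "donor":
                donor = DonorStatus(rec.status)
            elif rec.feature == "coverage":
                coverage = rec.status == "low"
            elif rec.feature == "lesion":
                lesions.append(
                    Lesion(
                        LesionType(rec.lesion_type),
                        int(rec.start) - 1, int(rec.end),
                        int(rec.length_bp), rec.detail,
                    )
                )
        reports.append(
            LesionReport(
                species_id=str(species),
                start_codons=(starts[1], starts[2]),
                lesions=lesions,
                promoter_status=promoter,
                donor_status=donor,
                coverage_flag=coverage,
            )
        )
    return reports


def calls_to_frame(calls: dict[str, FunctionalityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": call.species_id,
                "state": call.state.value,
                "initiation_site": call.initiation_site or "",
                "reasons": "; ".join(call.reasons),
            }
            for call in calls.values()
        ]
    )


def write_calls(calls: dict[str, FunctionalityCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> dict[str, State]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    return {rec.species: State(rec.state) for rec in df.itertuples(index=False)}


def events_to_frame(events: list[LossEvent]) -> pd.DataFrame:
    rows = []
    for i, event in enumerate(events, start=1):
        shared = event.shared_lesion
        rows.append(
            {
                "event_id": i,
                "anchor_branch": event.anchor,
                "leaves": ";".join(event.supporting_leaves),
                "shared_lesion": (
                    f"{shared.type.value}:{shared.start + 1}-{shared.end}"
                    if shared is not None
                    else ""
                ),
                "flags": ";".join(event.flags),
            }
        )
    return pd.DataFrame(
        rows, columns=["event_id", "anchor_branch", "leaves", "shared_lesion", "flags"]
    )


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"library", "exon_1A", "exon_1B", "exon_6"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    for col in ("exon_1A", "exon_1B", "exon_6"):
        if (df[col] < 0).any() or not (df[col] == df[col].astype(int)).all():
            raise ValueError(f"column {col} must hold nonnegative integers")
    if df["library"].duplicated().any():
        raise ValueError("duplicate library ids")
    return df
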
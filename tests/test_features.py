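"""Lesion detectors: Kozak scoring, start codons, ORF disruptions,
donor and promoter assessment, and the aggregated report."""

import numpy as np
import pytest

from isoloss import (
    DonorStatus,
    KozakClass,
    LesionType,
    PromoterStatus,
    RegionRow,
    assess_promoter,
    build_feature_report,
    check_splice_donor,
    detect_orf_disruptions,
    scan_start_codons,
    score_kozak,
)
from oracles import stop_codon_indices


def mutate(columns, edits):
    seq = list(columns)
    for col, base in edits.items():
        seq[col] = base
    return "".join(seq)


class TestKozak:
    @pytest.mark.parametrize(
        "context,expected",
        [
            ("GCCACCATGG", KozakClass.STRONG),  # textbook optimal
            ("GCCTCCATGC", KozakClass.WEAK),
            ("GCCGCCATGA", KozakClass.ADEQUATE),
            ("CCCATGG", KozakClass.ADEQUATE),  # left-truncated, -3 missing
        ],
    )
    def test_examples(self, context, expected):
        assert score_kozak(context) == expected

    def test_all_16_key_position_combinations(self):
        # independent restatement of the consensus rule per combination
        for minus3 in "ACGT":
            for plus4 in "ACGT":
                context = f"GCC{minus3}CCATG{plus4}"
                hits = (minus3 in "AG") + (plus4 == "G")
                expected = [KozakClass.WEAK, KozakClass.ADEQUATE, KozakClass.STRONG][hits]
                assert score_kozak(context) == expected, context


class TestStartCodons:
    def test_reference_both_intact(self, template_ann):
        ref, ann = template_ann
        s1, s2 = scan_start_codons(ref, ref, ann)
        assert s1.intact and s2.intact
        assert s1.kozak_class in (KozakClass.STRONG, KozakClass.ADEQUATE)
        assert s2.kozak_class in (KozakClass.STRONG, KozakClass.ADEQUATE)

    def test_atg1_mutated_atg2_remains(self, template_ann):
        ref, ann = template_ann
        row = RegionRow("equus_like", mutate(ref.columns, {ann.atg1_pos + 1: "C"}))
        s1, s2 = scan_start_codons(row, ref, ann)
        assert not s1.intact and s1.observed_codon == "ACG"
        assert s2.intact

    def test_both_mutated(self, template_ann):
        ref, ann = template_ann
        row = RegionRow(
            "double",
            mutate(ref.columns, {ann.atg1_pos + 1: "C", ann.atg2_pos + 2: "A"}),
        )
        s1, s2 = scan_start_codons(row, ref, ann)
        assert not s1.intact and not s2.intact

    def test_gap_at_codon_reports_dash(self, template_ann):
        ref, ann = template_ann
        row = RegionRow("gapped", mutate(ref.columns, {ann.atg1_pos: "-"}))
        s1, _ = scan_start_codons(row, ref, ann)
        assert not s1.intact and "-" in s1.observed_codon

    def test_n_makes_status_ambiguous(self, template_ann):
        ref, ann = template_ann
        row = RegionRow("noisy", mutate(ref.columns, {ann.atg1_pos: "N"}))
        s1, _ = scan_start_codons(row, ref, ann)
        assert not s1.intact and s1.ambiguous


class TestOrfDisruptions:
    def test_identity_is_clean(self, template_ann):
        ref, ann = template_ann
        assert detect_orf_disruptions(ref, ref, ann) == []

    @pytest.mark.parametrize("length", [1, 2, 3, 4, 5, 6])
    def test_frameshift_parity(self, template_ann, length):
        ref, ann = template_ann
        start = ann.coding_block[0] + 30
        row = RegionRow(
            "indel", mutate(ref.columns, {start + i: "-" for i in range(length)})
        )
        lesions = detect_orf_disruptions(row, ref, ann)
        fs = [l for l in lesions if l.type is LesionType.FRAMESHIFT_INDEL]
        if length % 3:
            assert len(fs) == 1 and fs[0].length_bp == length
        else:
            assert fs == []

    def test_two_bp_deletion_creates_shifted_stop(self, template_ann):
        # deletion then TGA read in the shifted frame, verified by the
        # independent translation oracle
        ref, ann = template_ann
        c0 = ann.coding_block[0]
        edits = {c0 + 30: "-", c0 + 31: "-"}
        # engineer the next shifted codon to be TGA: bases at c0+32..34
        edits.update({c0 + 32: "T", c0 + 33: "G", c0 + 34: "A"})
        row = RegionRow("fs", mutate(ref.columns, edits))
        lesions = detect_orf_disruptions(row, ref, ann)
        types = [l.type for l in lesions]
        assert LesionType.FRAMESHIFT_INDEL in types
        assert LesionType.PREMATURE_STOP in types
        assert 10 in stop_codon_indices(row.columns, ann)

    def test_in_frame_stop_reported(self, template_ann):
        ref, ann = template_ann
        c0 = ann.coding_block[0]
        row = RegionRow(
            "echinops_like",
            mutate(ref.columns, {c0 + 60: "T", c0 + 61: "A", c0 + 62: "G"}),
        )
        lesions = detect_orf_disruptions(row, ref, ann)
        stops = [l for l in lesions if l.type is LesionType.PREMATURE_STOP]
        assert len(stops) == 1 and stops[0].start == c0 + 60

    def test_fully_gapped_coding_is_region_absent(self, template_ann):
        ref, ann = template_ann
        row = RegionRow(
            "gone",
            mutate(ref.columns, {c: "-" for c in range(*ann.coding_block)}),
        )
        lesions = detect_orf_disruptions(row, ref, ann)
        assert [l.type for l in lesions] == [LesionType.REGION_ABSENT]

    def test_stop_calls_match_translation_oracle(self, template_ann):
        """200 random mutated rows: premature-stop codon indices equal a
        brute-force oracle that ungaps the row, applies cumulative frame
        offsets and translates."""
        ref, ann = template_ann
        c0, c1 = ann.coding_block
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq = list(ref.columns)
            for _ in range(rng.integers(0, 12)):  # point substitutions
                col = int(rng.integers(c0, c1))
                seq[col] = "ACGT"[rng.integers(4)]
            for _ in range(rng.integers(0, 3)):  # deletions of 1-5 bp
                col = int(rng.integers(c0, c1 - 5))
                for i in range(int(rng.integers(1, 6))):
                    seq[col + i] = "-"
            row = "".join(seq)
            lesions = detect_orf_disruptions(RegionRow("r", row), ref, ann)
            got = sorted(
                sum(1 for c in range(ann.atg1_pos, l.start) if row[c] != "-") // 3
                for l in lesions
                if l.type is LesionType.PREMATURE_STOP
            )
            assert got == stop_codon_indices(row, ann)


class TestSpliceDonor:
    def test_only_gt_passes(self, template_ann):
        ref, ann = template_ann
        for b1 in "ACGT":
            for b2 in "ACGT":
                row = RegionRow(
                    "d", mutate(ref.columns, {ann.donor_pos: b1, ann.donor_pos + 1: b2})
                )
                status = check_splice_donor(row, ref, ann)
                expected = DonorStatus.INTACT if (b1, b2) == ("G", "T") else DonorStatus.LOST
                assert status == expected

    def test_gapped_donor_is_lost(self, template_ann):
        ref, ann = template_ann
        row = RegionRow(
            "d", mutate(ref.columns, {ann.donor_pos: "-", ann.donor_pos + 1: "-"})
        )
        assert check_splice_donor(row, ref, ann) == DonorStatus.LOST

    def test_n_is_unknown(self, template_ann):
        ref, ann = template_ann
        row = RegionRow("d", mutate(ref.columns, {ann.donor_pos + 1: "N"}))
        assert check_splice_donor(row, ref, ann) == DonorStatus.UNKNOWN


class TestPromoter:
    def test_reference_intact(self, template_ann):
        ref, ann = template_ann
        status, lesions = assess_promoter(ref, ref, ann)
        assert status is PromoterStatus.INTACT and lesions == []

    def test_muroid_style_rearrangement(self, template_ann):
        ref, ann = template_ann
        edits = {c: "-" for c in range(500, 560)}  # delete conserved TSS segment
        edits.update({c: "ACGT"[c % 4] for c in range(560, 632)})  # 72 bp insertion
        row = RegionRow("muroid", mutate(ref.columns, edits))
        status, lesions = assess_promoter(row, ref, ann)
        assert status is PromoterStatus.REARRANGED
        ins = [l for l in lesions if l.type is LesionType.PROMOTER_INSERTION]
        assert len(ins) == 1 and ins[0].length_bp == 72

    def test_fully_gapped_promoter_absent(self, template_ann):
        ref, ann = template_ann
        row = RegionRow(
            "gone", mutate(ref.columns, {c: "-" for c in range(*ann.promoter_block)})
        )
        status, _ = assess_promoter(row, ref, ann)
        assert status is PromoterStatus.ABSENT

    def test_small_indels_tolerated(self, template_ann):
        ref, ann = template_ann
        row = RegionRow("ok", mutate(ref.columns, {c: "-" for c in range(505, 515)}))
        status, lesions = assess_promoter(row, ref, ann)
        assert status is PromoterStatus.INTACT and lesions == []

    @pytest.mark.parametrize("length", [30, 40, 80, 120])
    def test_enlarging_deletion_never_reverts(self, template_ann, length):
        ref, ann = template_ann
        row = RegionRow(
            "del", mutate(ref.columns, {c: "-" for c in range(505, 505 + length)})
        )
        status, _ = assess_promoter(row, ref, ann)
        assert status is not PromoterStatus.INTACT


class TestBuildReport:
    def test_reference_report_clean(self, template_ann):
        ref, ann = template_ann
        report = build_feature_report(ref, ref, ann)
        assert report.lesions == []
        assert all(s.intact for s in report.start_codons)
        assert report.promoter_status is PromoterStatus.INTACT
        assert report.donor_status is DonorStatus.INTACT

    def test_sus_style_row_single_donor_loss(self, template_ann):
        ref, ann = template_ann
        row = RegionRow("sus", mutate(ref.columns, {ann.donor_pos + 1: "C"}))
        report = build_feature_report(row, ref, ann)
        assert [l.type for l in report.lesions] == [LesionType.DONOR_LOSS]

    def test_aggregate_equals_union_of_detectors(self, template_ann):
        ref, ann = template_ann
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = list(ref.columns)
            for _ in range(10):
                col = int(rng.integers(0, len(seq)))
                if seq[col] != "-":
                    seq[col] = "ACGT"[rng.integers(4)]
            row = RegionRow("r", "".join(seq))
            report = build_feature_report(row, ref, ann)
            _, promoter_lesions = assess_promoter(row, ref, ann)
            orf = detect_orf_disruptions(row, ref, ann)
            s1, s2 = scan_start_codons(row, ref, ann)
            starts = [s for s in (s1, s2) if not s.intact and not s.ambiguous]
            donor_lost = check_splice_donor(row, ref, ann) is DonorStatus.LOST
            expected_n = len(promoter_lesions) + len(orf) + len(starts) + donor_lost
            assert len(report.lesions) == expected_n

    def test_determinism(self, template_ann):
        ref, ann = template_ann
        row = RegionRow("sus", mutate(ref.columns, {ann.donor_pos + 1: "C"}))
        assert build_feature_report(row, ref, ann) == build_feature_report(row, ref, ann)

    def test_whole_region_gapped_single_lesion(self, template_ann):
        ref, ann = template_ann
        lo, hi = ann.region_span()
        row = RegionRow("erinaceus", mutate(ref.columns, {c: "-" for c in range(lo, hi)}))
        report = build_feature_report(row, ref, ann)
        assert [l.type for l in report.lesions] == [LesionType.REGION_ABSENT]
        assert report.promoter_status is PromoterStatus.ABSENT
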
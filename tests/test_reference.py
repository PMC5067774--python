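"""Annotation loading, coordinate conventions, region derivation."""

import numpy as np
import pytest

from isotail import (
    MatureArm,
    MirnaReference,
    derive_regions,
    load_reference,
    write_reference,
)
from isotail.reference import ReferenceError, normalize_sequence, to_rna


def write_tsv_reference(tmp_path, fasta_records, rows):
    fasta = tmp_path / "pre.fasta"
    fasta.write_text("".join(f">{pid}\n{seq}\n" for pid, seq in fasta_records))
    tsv = tmp_path / "arms.tsv"
    lines = ["precursor_id\tarm_name\tstart\tend\ttemplate_context"]
    lines += ["\t".join(str(x) for x in row) for row in rows]
    tsv.write_text("\n".join(lines) + "\n")
    return fasta, tsv


class TestLoadTsv:
    def test_spec_toy_precursor(self, tmp_path):
        fasta, tsv = write_tsv_reference(
            tmp_path,
            [("toy-T", "AAGGCCUUAAGGCCUUCGAUCGAUU")],
            [("toy-T", "miR-T-5p", 0, 16, "CGAUCGAUUA")],
        )
        (ref,) = load_reference(fasta, tsv, "tsv")
        arm = ref.arm("miR-T-5p")
        assert arm.canonical_length == 16
        assert ref.template_context["miR-T-5p"].startswith("CGATCGATT")
        # U input normalised to the DNA alphabet, recoverable as RNA
        assert set(ref.precursor_seq) <= set("ACGT")
        assert to_rna(ref.precursor_seq) == "AAGGCCUUAAGGCCUUCGAUCGAUU"

    def test_boundary_arm_without_context_fails(self, tmp_path):
        # only 9 nt remain 3' of the arm: context must be explicit
        fasta, tsv = write_tsv_reference(
            tmp_path,
            [("toy-T", "AAGGCCUUAAGGCCUUCGAUCGAUU")],
            [("toy-T", "miR-T-5p", 0, 16, ".")],
        )
        with pytest.raises(ReferenceError, match="template context"):
            load_reference(fasta, tsv, "tsv")

    def test_arm_outside_precursor_fails(self, tmp_path):
        fasta, tsv = write_tsv_reference(
            tmp_path,
            [("toy-T", "AAGGCCUUAAGGCCUUCGAUCGAUU")],
            [("toy-T", "miR-T-5p", 10, 40, ".")],
        )
        with pytest.raises(ReferenceError, match="outside precursor"):
            load_reference(fasta, tsv, "tsv")

    def test_missing_precursor_named_in_error(self, tmp_path):
        fasta, tsv = write_tsv_reference(
            tmp_path,
            [("toy-T", "AAGGCCUUAAGGCCUUCGAUCGAUU")],
            [("toy-X", "miR-X-5p", 0, 16, ".")],
        )
        with pytest.raises(ReferenceError, match="toy-X"):
            load_reference(fasta, tsv, "tsv")

    def test_duplicate_arm_names_fail(self, tmp_path):
        seq = "AAGGCCTTAAGGCCTTCGATCGATTACGATCGGATTACAG"
        fasta, tsv = write_tsv_reference(
            tmp_path, [("p", seq)],
            [("p", "arm-5p", 0, 16, ""), ("p", "arm-5p", 2, 18, "")],
        )
        with pytest.raises(ReferenceError, match="duplicate"):
            load_reference(fasta, tsv, "tsv")

    def test_round_trip(self, tmp_path, demo_ref, spec_ref):
        write_reference([demo_ref, spec_ref], tmp_path / "rt.fasta", tmp_path / "rt.tsv")
        reloaded = load_reference(tmp_path / "rt.fasta", tmp_path / "rt.tsv", "tsv")
        assert {r.precursor_id: r for r in reloaded} == {
            r.precursor_id: r for r in [demo_ref, spec_ref]
        }


class TestLoadGff3:
    GENOME = (
        "TTTTT"
        "ACGTACGTGGATCCAAGCTTGCGCATATCGCGTAGCTAGCTAAGGCCTTCAGATCCGATA"
        "GGGGGGGGGG"
    )

    def _write(self, tmp_path, strand):
        fasta = tmp_path / "genome.fasta"
        fasta.write_text(f">chrT\n{self.GENOME}\n")
        # precursor = genome[5:65] (1-based 6..65); arm = first 16 nt of the
        # precursor in precursor orientation
        if strand == "+":
            arm_start, arm_end = 6, 21  # 1-based inclusive, rel [0,16)
        else:
            arm_start, arm_end = 50, 65
        gff = tmp_path / "anno.gff3"
        gff.write_text(
            "##gff-version 3\n"
            f"chrT\t.\tmiRNA_primary_transcript\t6\t65\t.\t{strand}\t.\t"
            "ID=MI999;Name=toy-mir\n"
            f"chrT\t.\tmiRNA\t{arm_start}\t{arm_end}\t.\t{strand}\t.\t"
            "ID=MIMAT999;Name=toy-miR-5p;Derives_from=MI999\n"
        )
        return fasta, gff

    def test_plus_strand_coordinates(self, tmp_path):
        fasta, gff = self._write(tmp_path, "+")
        (ref,) = load_reference(fasta, gff, "gff3")
        arm = ref.arm("toy-miR-5p")
        assert (arm.start, arm.end) == (0, 16)
        assert ref.precursor_seq == self.GENOME[5:65]
        assert ref.arm_sequence(arm) == self.GENOME[5:21]

    def test_minus_strand_reverse_complemented(self, tmp_path):
        from Bio.Seq import Seq

        fasta, gff = self._write(tmp_path, "-")
        (ref,) = load_reference(fasta, gff, "gff3")
        arm = ref.arm("toy-miR-5p")
        assert (arm.start, arm.end) == (0, 16)
        rc = str(Seq(self.GENOME[5:65]).reverse_complement())
        assert ref.precursor_seq == rc
        assert ref.arm_sequence(arm) == rc[:16]

    def test_boundary_arm_context_taken_from_genome_flank(self, tmp_path):
        fasta = tmp_path / "genome.fasta"
        fasta.write_text(f">chrT\n{self.GENOME}\n")
        gff = tmp_path / "anno.gff3"
        # arm ends flush with the precursor 3' end; context must come from
        # the genomic flank (the G-run downstream)
        gff.write_text(
            "##gff-version 3\n"
            "chrT\t.\tmiRNA_primary_transcript\t6\t65\t.\t+\t.\tID=MI1;Name=m1\n"
            "chrT\t.\tmiRNA\t48\t65\t.\t+\t.\tID=MA1;Name=m1-3p;Derives_from=MI1\n"
        )
        (ref,) = load_reference(fasta, gff, "gff3")
        arm = ref.arm("m1-3p")
        assert arm.end == len(ref.precursor_seq)
        assert ref.template_context["m1-3p"] == "GGGGGGGGGG"


class TestDeriveRegions:
    def test_two_arms(self, two_arm_ref):
        regions = derive_regions(two_arm_ref)
        assert regions.upstream_of_5p is None
        assert regions.mature_5p == (0, 16)
        assert regions.loop == (16, 20)
        assert regions.mature_3p == (20, 36)
        assert regions.downstream_of_3p == (36, 40)

    def test_single_arm(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        ref = MirnaReference("p", seq, (MatureArm("p-5p", 4, 26),))
        regions = derive_regions(ref)
        assert regions.upstream_of_5p == (0, 4)
        assert regions.mature_5p == (4, 26)
        assert regions.loop is None
        assert regions.mature_3p is None
        assert regions.downstream_of_3p == (26, 60)

    def test_overlapping_arms_fail(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        ref = MirnaReference(
            "p", seq, (MatureArm("a-5p", 0, 20), MatureArm("b-3p", 15, 35))
        )
        with pytest.raises(ReferenceError, match="overlap"):
            derive_regions(ref)

    def test_regions_partition_precursor(self, demo_ref, two_arm_ref):
        for ref in (demo_ref, two_arm_ref):
            regions = derive_regions(ref)
            covered = []
            for _, (lo, hi) in regions.items():
                covered.extend(range(lo, hi))
            assert covered == list(range(len(ref.precursor_seq)))


class TestValidation:
    def test_arm_length_bounds(self):
        with pytest.raises(ReferenceError, match="length"):
            MatureArm("short", 0, 10)
        with pytest.raises(ReferenceError, match="length"):
            MatureArm("long", 0, 31)

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ReferenceError, match="non-ACGT"):
            normalize_sequence("ACGTNNN")

    def test_context_must_agree_with_precursor(self):
        with pytest.raises(ReferenceError, match="disagrees"):
            MirnaReference(
                "p", "ACGTACGTACGTACGTACGTACGTACGTAC",
                (MatureArm("p-5p", 0, 16),),
                {"p-5p": "TTTTTTTTTT"},
            )

    def test_5p_must_precede_3p(self):
        with pytest.raises(ReferenceError, match="5p arm must start before"):
            MirnaReference(
                "p", "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT",
                (MatureArm("x-3p", 0, 16), MatureArm("x-5p", 20, 36)),
                {"x-5p": "ACGTACGTAC"},
            )
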
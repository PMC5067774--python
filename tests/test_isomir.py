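"""Read anchoring and greedy 3'-end decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isotail import (
    IsomirKey,
    MatureArm,
    MirnaReference,
    classify_key,
    decompose_3prime,
    match_read,
    match_reads,
    reconstruct_read,
)
from isotail.isomir import AMBIGUOUS, ASSIGNED, SHIFTED, UNASSIGNED
from .conftest import brute_force_decompose, random_toy_reference


class TestDecompose:
    """Template after the toy arm starts 'CGAT...' (spec_ref fixture)."""

    def test_templated_extension(self, spec_ref):
        arm = spec_ref.arm("miR-T-5p")
        read = spec_ref.arm_sequence(arm) + "C"
        assert decompose_3prime(read, spec_ref, arm, 0) == (1, "")

    def test_nontemplated_tail_after_extension(self, spec_ref):
        # template has "CG": the C is templated, the A is not
        arm = spec_ref.arm("miR-T-5p")
        read = spec_ref.arm_sequence(arm) + "CA"
        assert decompose_3prime(read, spec_ref, arm, 0) == (1, "A")

    def test_trimmed(self, spec_ref):
        arm = spec_ref.arm("miR-T-5p")
        read = spec_ref.arm_sequence(arm)[:-2]
        assert decompose_3prime(read, spec_ref, arm, 0) == (-2, "")

    def test_canonical(self, spec_ref):
        arm = spec_ref.arm("miR-T-5p")
        assert decompose_3prime(spec_ref.arm_sequence(arm), spec_ref, arm, 0) == (0, "")

    def test_tail_beyond_context_is_nontemplated(self, spec_ref):
        # context is 10 nt; anything the read carries past it is tail even
        # if it would extend the template
        arm = spec_ref.arm("miR-T-5p")
        ctx = spec_ref.template_context["miR-T-5p"]
        read = spec_ref.arm_sequence(arm) + ctx + "GGG"
        delta3, tail = decompose_3prime(read, spec_ref, arm, 0)
        assert delta3 == len(ctx)
        assert tail == "GGG"

    def test_agrees_with_brute_force_oracle(self):
        """Greedy decomposition == exhaustive maximal-templated-split oracle
        on >=1000 randomised reads over >=20 toy references."""
        rng = np.random.default_rng(2016)
        n_checked = 0
        for r in range(20):
            ref = random_toy_reference(rng, r)
            (arm,) = ref.arms
            template = ref.extended_template(arm)
            for _ in range(60):
                offset5 = int(rng.integers(-2, 3))
                start = arm.start + offset5
                core = int(rng.integers(14, arm.canonical_length - 1))
                overhang_t = int(rng.integers(0, 5))   # templated stretch
                overhang_r = int(rng.integers(0, 4))   # random stretch
                read = template[start : start + core + overhang_t]
                read += "".join(rng.choice(list("ACGT"), size=overhang_r))
                got = decompose_3prime(read, ref, arm, offset5)
                want = brute_force_decompose(read, template, arm.start, arm.end, offset5)
                assert got == want
                n_checked += 1
        assert n_checked >= 1000

    def test_reconstruction_inverts_decomposition(self):
        """Arm shifted by offset5, extended by delta3 template nucleotides,
        plus tail reproduces the read exactly."""
        rng = np.random.default_rng(99)
        for r in range(10):
            ref = random_toy_reference(rng, r)
            (arm,) = ref.arms
            template = ref.extended_template(arm)
            for _ in range(50):
                offset5 = int(rng.integers(-2, 3))
                start = arm.start + offset5
                end = start + int(rng.integers(14, arm.canonical_length + 4))
                read = template[start:end] + "".join(
                    rng.choice(list("ACGT"), size=int(rng.integers(0, 3)))
                )
                delta3, tail = decompose_3prime(read, ref, arm, offset5)
                key = IsomirKey(ref.precursor_id, arm.name, offset5, delta3, tail)
                assert reconstruct_read(key, ref) == read
                # length bookkeeping of the key
                assert len(read) == (
                    arm.canonical_length - offset5 + delta3 + len(tail)
                )


class TestMatchRead:
    def test_canonical_read_assigned(self, demo_ref):
        arm = demo_ref.arm("5p")
        a = match_read(demo_ref.arm_sequence(arm), [demo_ref])
        assert a.status == ASSIGNED
        assert a.key == IsomirKey("mir-sim-1", "miR-sim-5p", 0, 0, "")
        assert a.n_candidate_arms == 1

    def test_shift_outside_window_unassigned(self, demo_ref):
        arm = demo_ref.arm("5p")
        read = demo_ref.precursor_seq[arm.start - 3 : arm.end]  # offset5 = -3
        a = match_read(read, [demo_ref])
        assert a.status == UNASSIGNED

    def test_shift_inside_window_assigned(self, demo_ref):
        arm = demo_ref.arm("5p")
        read = demo_ref.precursor_seq[arm.start - 2 : arm.end]
        a = match_read(read, [demo_ref])
        assert a.status == ASSIGNED
        assert a.key.offset5 == -2
        assert a.key.delta3_templated == 0

    def test_duplicate_precursors_ambiguous(self, demo_ref):
        twin = MirnaReference(
            "mir-sim-2", demo_ref.precursor_seq,
            tuple(MatureArm(a.name.replace("sim", "sim2"), a.start, a.end)
                  for a in demo_ref.arms),
        )
        arm = demo_ref.arm("5p")
        a = match_read(demo_ref.arm_sequence(arm), [demo_ref, twin])
        assert a.status == AMBIGUOUS
        assert a.n_candidate_arms == 2
        assert len(a.candidates) == 2

    def test_bad_reads_recorded_not_raised(self, demo_ref):
        for read, reason_part in [
            ("", "empty"),
            ("ACGTNACGTACGTACGTACGT", "non-ACGT"),
            ("ACGTACGT", "shorter"),
        ]:
            a = match_read(read, [demo_ref])
            assert a.status == UNASSIGNED
            assert reason_part in a.reason

    def test_rna_alphabet_accepted(self, demo_ref):
        arm = demo_ref.arm("5p")
        read = demo_ref.arm_sequence(arm).replace("T", "U")
        assert match_read(read, [demo_ref]).status == ASSIGNED

    def test_status_partition_is_total(self, demo_ref):
        rng = np.random.default_rng(5)
        arm = demo_ref.arm("5p")
        reads = []
        for i in range(200):
            kind = i % 4
            if kind == 0:
                reads.append((f"r{i}", demo_ref.arm_sequence(arm)))
            elif kind == 1:
                reads.append((f"r{i}", "".join(rng.choice(list("ACGT"), size=22))))
            elif kind == 2:
                reads.append((f"r{i}", ""))
            else:
                reads.append((f"r{i}", demo_ref.arm_sequence(arm) + "CA"))
        statuses = [a.status for a in match_reads(reads, [demo_ref])]
        assert len(statuses) == 200
        counts = {s: statuses.count(s) for s in (ASSIGNED, AMBIGUOUS, UNASSIGNED)}
        assert sum(counts.values()) == 200


class TestClassifyKey:
    @pytest.mark.parametrize(
        "offset5,delta3,tail,expected",
        [
            (0, 0, "", "canonical"),
            (0, 1, "", "templated_extended"),   # the "+C" species
            (0, 1, "A", "nt_tailed"),           # the "+CA" species
            (0, -1, "", "trimmed"),
            (0, -3, "AA", "nt_tailed"),
            (1, 0, "", SHIFTED),
            (-2, 1, "A", SHIFTED),
        ],
    )
    def test_classes(self, offset5, delta3, tail, expected):
        key = IsomirKey("p", "a", offset5, delta3, tail)
        assert classify_key(key) == expected

    @given(
        offset5=st.integers(-2, 2),
        delta3=st.integers(-5, 5),
        tail=st.text(alphabet="ACGT", max_size=3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_every_key_gets_exactly_one_class(self, offset5, delta3, tail):
        key = IsomirKey("p", "a", offset5, delta3, tail)
        assert classify_key(key) in {
            "canonical", "templated_extended", "nt_tailed", "trimmed", SHIFTED,
        }
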
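"""Decompose the 3' ends of a few reads against a toy precursor.

Builds a 25-nt precursor whose template continues "CGAT..." after the
16-nt mature arm, then classifies reads that end exactly at the canonical
end, carry a templated extension, carry a non-templated tail, or are
trimmed.  The printed (offset5, delta3, tail) triple plus class shows how
a templated +C differs from a non-templated +A.
"""

from isotail import MatureArm, MirnaReference, classify_key, match_read

ref = MirnaReference(
    "toy-T",
    "AAGGCCUUAAGGCCUUCGAUCGAUU",
    (MatureArm("miR-T-5p", 0, 16),),
    {"miR-T-5p": "CGATCGATTA"},
)
arm = ref.arm("miR-T-5p")
mature = ref.arm_sequence(arm)

reads = {
    "canonical": mature,
    "templated +C": mature + "C",
    "+C then non-templated A": mature + "CA",
    "trimmed by 2": mature[:-2],
    "5' shifted": ref.precursor_seq[2 : 2 + 16] if len(ref.precursor_seq) >= 18 else mature,
}

for label, read in reads.items():
    a = match_read(read, [ref])
    if a.status != "assigned":
        print(f"{label:26s} -> {a.status} ({a.reason})")
        continue
    k = a.key
    print(
        f"{label:26s} -> offset5={k.offset5:+d} delta3={k.delta3_templated:+d} "
        f"tail={k.tail or '-':3s} class={classify_key(k)}"
    )
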
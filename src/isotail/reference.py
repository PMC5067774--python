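"""miRNA precursor annotations in precursor-relative coordinates.

Everything downstream of this module works on a :class:`MirnaReference`:
a precursor sequence, one or two mature-arm intervals, and for each arm a
stretch of *template context* — the nucleotides immediately 3' of the
mature end, against which templated extensions are judged.  Genomic strand
is resolved here, at load time; all other modules see plain 0-based,
half-open, precursor-relative intervals on the plus strand.

Sequences are held internally in the DNA alphabet (ACGT); U is accepted on
input and can be emitted on request.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

MIN_TEMPLATE_CONTEXT = 10
MIN_ARM_LENGTH = 16
MAX_ARM_LENGTH = 30

_U2T = str.maketrans("Uu", "Tt")


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


def normalize_sequence(seq: str, *, what: str = "sequence") -> str:
    """Uppercase, convert U to T, and reject anything outside ACGT."""
    s = str(seq).translate(_U2T).upper()
    bad = set(s) - set("ACGT")
    if bad:
        raise ReferenceError(
            f"{what} contains non-ACGT/U characters: {sorted(bad)}"
        )
    return s


def to_rna(seq: str) -> str:
    """DNA-alphabet internal sequence rendered as RNA."""
    return seq.replace("T", "U")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class MatureArm:
    """A mature miRNA interval on its precursor (0-based, half-open)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ReferenceError(
                f"arm {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        n = self.canonical_length
        if not MIN_ARM_LENGTH <= n <= MAX_ARM_LENGTH:
            raise ReferenceError(
                f"arm {self.name!r}: canonical length {n} nt outside "
                f"[{MIN_ARM_LENGTH}, {MAX_ARM_LENGTH}]"
            )

    @property
    def canonical_length(self) -> int:
        return self.end - self.start

    @property
    def side(self) -> Optional[str]:
        """'5p' or '3p' when the arm name says so, else None."""
        low = self.name.lower()
        if low.endswith("5p"):
            return "5p"
        if low.endswith("3p"):
            return "3p"
        return None


@dataclass(frozen=True)
class MirnaReference:
    """A precursor with mature arms and per-arm 3' template context.

    ``template_context[arm.name]`` starts at precursor position ``arm.end``
    and runs 3'-ward; where it overlaps the precursor it must agree with
    the precursor sequence, and it may extend past the precursor 3' end
    (supplied explicitly for arms that end at or near the boundary).
    """

    precursor_id: str
    precursor_seq: str
    arms: tuple[MatureArm, ...]
    template_context: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "precursor_seq",
            normalize_sequence(self.precursor_seq, what=f"precursor {self.precursor_id!r}"),
        )
        object.__setattr__(self, "arms", tuple(sorted(self.arms, key=lambda a: a.start)))
        n = len(self.precursor_seq)
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ReferenceError(
                f"precursor {self.precursor_id!r}: duplicate arm names {names}"
            )
        for arm in self.arms:
            if arm.end > n:
                raise ReferenceError(
                    f"precursor {self.precursor_id!r}: arm {arm.name!r} interval "
                    f"[{arm.start}, {arm.end}) outside precursor of length {n}"
                )
        sides = [a.side for a in self.arms]
        if "5p" in sides and "3p" in sides:
            if self.arm("5p").start >= self.arm("3p").start:
                raise ReferenceError(
                    f"precursor {self.precursor_id!r}: 5p arm must start before 3p arm"
                )
        ctx = dict(self.template_context)
        for arm in self.arms:
            available = self.precursor_seq[arm.end:]
            supplied = ctx.get(arm.name)
            if supplied is not None:
                supplied = normalize_sequence(
                    supplied, what=f"template context for {arm.name!r}"
                )
                overlap = min(len(supplied), len(available))
                if supplied[:overlap] != available[:overlap]:
                    raise ReferenceError(
                        f"precursor {self.precursor_id!r}: template context for "
                        f"{arm.name!r} disagrees with precursor sequence 3' of the arm"
                    )
                context = supplied if len(supplied) >= len(available) else available
            else:
                context = available
            if len(context) < MIN_TEMPLATE_CONTEXT:
                raise ReferenceError(
                    f"precursor {self.precursor_id!r}: arm {arm.name!r} has only "
                    f"{len(context)} nt of template context "
                    f"(need >= {MIN_TEMPLATE_CONTEXT}; supply it explicitly for "
                    f"arms ending at the precursor boundary)"
                )
            ctx[arm.name] = context
        object.__setattr__(self, "template_context", ctx)

    # -- lookups ---------------------------------------------------------

    def arm(self, name_or_side: str) -> MatureArm:
        """Fetch an arm by exact name or by side ('5p'/'3p')."""
        for arm in self.arms:
            if arm.name == name_or_side:
                return arm
        matches = [a for a in self.arms if a.side == name_or_side]
        if len(matches) == 1:
            return matches[0]
        raise KeyError(
            f"precursor {self.precursor_id!r} has no unique arm {name_or_side!r}"
        )

    def arm_sequence(self, arm: MatureArm) -> str:
        return self.precursor_seq[arm.start : arm.end]

    def extended_template(self, arm: MatureArm) -> str:
        """Precursor sequence up to ``arm.end`` followed by the template context.

        This is the string against which a read anchored at this arm is
        compared: positions < ``arm.end`` come from the precursor, positions
        >= ``arm.end`` from the context (which may reach past the precursor
        3' end).  Templated extension beyond the end of this string cannot
        be recognised and falls into the non-templated tail.
        """
        return self.precursor_seq[: arm.end] + self.template_context[arm.name]


@dataclass(frozen=True)
class PrecursorRegions:
    """The five precursor sub-regions used as a processing proxy.

    Intervals are 0-based half-open and precursor-relative; an absent
    region is None.  Order is 5'→3': upstream flank, mature 5p, loop,
    mature 3p, downstream flank.
    """

    upstream_of_5p: Optional[tuple[int, int]]
    mature_5p: Optional[tuple[int, int]]
    loop: Optional[tuple[int, int]]
    mature_3p: Optional[tuple[int, int]]
    downstream_of_3p: Optional[tuple[int, int]]

    ORDER = ("upstream_of_5p", "mature_5p", "loop", "mature_3p", "downstream_of_3p")

    def items(self) -> list[tuple[str, tuple[int, int]]]:
        """Non-empty (name, interval) pairs in 5'→3' order."""
        out = []
        for name in self.ORDER:
            iv = getattr(self, name)
            if iv is not None and iv[1] > iv[0]:
                out.append((name, iv))
        return out


def derive_regions(ref: MirnaReference) -> PrecursorRegions:
    """Partition a precursor into flanks, mature arms and loop.

    With both arms annotated the loop is the gap between the 5p end and
    the 3p start; with a single arm the loop is empty and the flanks are
    whatever lies outside the arm.  Overlapping arms are rejected.
    """
    if not ref.arms:
        raise ReferenceError(f"precursor {ref.precursor_id!r} has no annotated arms")
    n = len(ref.precursor_seq)
    arms = ref.arms  # sorted by start
    for a, b in zip(arms, arms[1:]):
        if b.start < a.end:
            raise ReferenceError(
                f"precursor {ref.precursor_id!r}: arms {a.name!r} and {b.name!r} overlap"
            )

    def iv(lo: int, hi: int) -> Optional[tuple[int, int]]:
        return (lo, hi) if hi > lo else None

    if len(arms) >= 2:
        five, three = arms[0], arms[-1]
        return PrecursorRegions(
            upstream_of_5p=iv(0, five.start),
            mature_5p=(five.start, five.end),
            loop=iv(five.end, three.start),
            mature_3p=(three.start, three.end),
            downstream_of_3p=iv(three.end, n),
        )
    (arm,) = arms
    if arm.side == "3p":
        return PrecursorRegions(
            upstream_of_5p=iv(0, arm.start),
            mature_5p=None,
            loop=None,
            mature_3p=(arm.start, arm.end),
            downstream_of_3p=iv(arm.end, n),
        )
    # single arm defaults to the 5p slot unless named otherwise
    return PrecursorRegions(
        upstream_of_5p=iv(0, arm.start),
        mature_5p=(arm.start, arm.end),
        loop=None,
        mature_3p=None,
        downstream_of_3p=iv(arm.end, n),
    )


# ---------------------------------------------------------------------------
# loading


def load_reference(
    precursor_fasta: str | os.PathLike,
    annotation: str | os.PathLike,
    dialect: str = "tsv",
) -> list[MirnaReference]:
    """Load precursor sequences plus arm annotations.

    dialect='tsv': FASTA records are precursors; the TSV has columns
    precursor_id, arm_name, start, end (0-based half-open,
    precursor-relative) and optionally template_context.

    dialect='gff3': miRBase-style GFF3 with miRNA_primary_transcript and
    miRNA features; FASTA records are the sequences the GFF3 seqid column
    refers to (a genome slice or the precursors themselves).  1-based
    inclusive coordinates are converted and minus-strand records are
    reverse-complemented into precursor orientation.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(precursor_fasta), "fasta"):
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ReferenceError(f"no FASTA records in {precursor_fasta}")
    if dialect == "tsv":
        return _load_tsv(seqs, annotation)
    if dialect == "gff3":
        return _load_gff3(seqs, annotation)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _load_tsv(seqs: dict[str, str], path: str | os.PathLike) -> list[MirnaReference]:
    arms: dict[str, list[MatureArm]] = {}
    contexts: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"precursor_id", "arm_name", "start", "end"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ReferenceError(
                f"annotation TSV must have columns {sorted(required)}"
            )
        for row in reader:
            pid = row["precursor_id"]
            if pid not in seqs:
                raise ReferenceError(
                    f"annotated precursor {pid!r} missing from FASTA"
                )
            arm = MatureArm(row["arm_name"], int(row["start"]), int(row["end"]))
            arms.setdefault(pid, []).append(arm)
            ctx = (row.get("template_context") or "").strip()
            if ctx and ctx != ".":
                contexts.setdefault(pid, {})[arm.name] = ctx
    return [
        MirnaReference(pid, seqs[pid], tuple(arm_list), contexts.get(pid, {}))
        for pid, arm_list in arms.items()
    ]


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def _load_gff3(seqs: dict[str, str], path: str | os.PathLike) -> list[MirnaReference]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    refs: list[MirnaReference] = []
    primaries = list(db.features_of_type("miRNA_primary_transcript"))
    if not primaries:
        raise ReferenceError("GFF3 contains no miRNA_primary_transcript features")
    matures = list(db.features_of_type("miRNA"))
    for pre in primaries:
        pre_id = pre.attributes.get("ID", [None])[0]
        pre_name = pre.attributes.get("Name", [pre_id])[0] or pre_id
        if pre.seqid not in seqs:
            raise ReferenceError(
                f"GFF3 seqid {pre.seqid!r} (precursor {pre_name!r}) missing from FASTA"
            )
        chrom = normalize_sequence(seqs[pre.seqid], what=f"FASTA record {pre.seqid!r}")
        lo, hi = pre.start - 1, pre.end  # to 0-based half-open
        if hi > len(chrom):
            raise ReferenceError(
                f"precursor {pre_name!r} interval exceeds FASTA record {pre.seqid!r}"
            )
        pre_seq = chrom[lo:hi]
        if pre.strand == "-":
            pre_seq = reverse_complement(pre_seq)
        arm_list = []
        for m in matures:
            derives = m.attributes.get("Derives_from", [None])[0]
            if derives != pre_id and not (
                m.seqid == pre.seqid and pre.start <= m.start and m.end <= pre.end
                and derives is None
            ):
                continue
            name = m.attributes.get("Name", m.attributes.get("ID", ["?"]))[0]
            if pre.strand == "-":
                start = pre.end - m.end
                end = pre.end - m.start + 1
            else:
                start = m.start - pre.start
                end = m.end - pre.start + 1
            if start < 0 or end > len(pre_seq):
                raise ReferenceError(
                    f"arm {name!r} falls outside precursor {pre_name!r}"
                )
            arm_list.append(MatureArm(name, start, end))
        # context past the precursor 3' end, from the flanking genome sequence
        contexts: dict[str, str] = {}
        for arm in arm_list:
            if len(pre_seq) - arm.end < MIN_TEMPLATE_CONTEXT:
                want = arm.end + MIN_TEMPLATE_CONTEXT
                if pre.strand == "-":
                    glo = max(0, pre.end - want)
                    flank = reverse_complement(chrom[glo : pre.end])
                else:
                    flank = chrom[lo : lo + want]
                contexts[arm.name] = flank[arm.end :]
        refs.append(MirnaReference(pre_name, pre_seq, tuple(arm_list), contexts))
    return refs


def write_reference(
    refs: Iterable[MirnaReference],
    fasta_path: str | os.PathLike,
    tsv_path: str | os.PathLike,
) -> None:
    """Write references back out as precursor FASTA + annotation TSV.

    Template context is written explicitly, so a load/write/load round
    trip reproduces the references exactly.
    """
    refs = list(refs)
    with open(fasta_path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.precursor_id}\n{ref.precursor_seq}\n")
    with open(tsv_path, "w") as fh:
        fh.write("precursor_id\tarm_name\tstart\tend\ttemplate_context\n")
        for ref in refs:
            for arm in ref.arms:
                ctx = ref.template_context[arm.name]
                fh.write(
                    f"{ref.precursor_id}\t{arm.name}\t{arm.start}\t{arm.end}\t{ctx}\n"
                )
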
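"""Anchor reads to mature arms and decompose their 3' ends.

A small-RNA read anchored at a mature arm is described by three things:
how far its 5' end is shifted from the canonical start (``offset5``), how
far its *templated* portion runs past or short of the canonical 3' end
(``delta3_templated``), and whatever non-templated nucleotides remain
(``tail``).  The decomposition is greedy templated-first: the read is
walked along the precursor/template context for as long as it agrees, and
everything after the first disagreement is tail.  A 3' addition that
matches the template is therefore always called templated, never tail —
the only deterministic rule under which a templated +C extension and a
subsequent non-templated +A are told apart.

No mismatches are tolerated inside the templated portion: reads carrying
internal sequencing errors fall to ``unassigned`` rather than polluting
the end-state classes that the tailing/trimming ratios are built from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .reference import MatureArm, MirnaReference

DEFAULT_MAX_OFFSET5 = 2
DEFAULT_MIN_CORE_MATCH = 14

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"

_U2T = str.maketrans("Uu", "Tt")


@dataclass(frozen=True, order=True)
class IsomirKey:
    """Identity of one isomiR species.

    offset5: read 5' start minus arm start (negative = upstream shift).
    delta3_templated: templated 3' end minus canonical end (negative =
    trimmed, positive = templated extension).
    tail: non-templated 3' nucleotides, possibly empty.
    """

    precursor_id: str
    arm_name: str
    offset5: int
    delta3_templated: int
    tail: str


@dataclass
class ReadAssignment:
    read_id: str
    key: Optional[IsomirKey]
    status: str
    n_candidate_arms: int
    reason: Optional[str] = None
    #: precursor interval covered by the templated portion (clipped to the
    #: precursor), for region counting; None when unassigned
    templated_span: Optional[tuple[int, int]] = None
    #: all candidate keys for ambiguous reads (empty otherwise), so callers
    #: can opt in to fractional 1/n counting
    candidates: tuple[IsomirKey, ...] = ()


def decompose_3prime(
    read_seq: str, ref: MirnaReference, arm: MatureArm, offset5: int
) -> tuple[int, str]:
    """Greedy templated-first 3'-end decomposition of an anchored read.

    Returns (delta3_templated, tail).  Total on any read whose 5' end sits
    at ``arm.start + offset5``; the templated portion may be empty.
    """
    template = ref.extended_template(arm)
    start = arm.start + offset5
    if start < 0:
        raise ValueError(f"read start {start} before precursor 5' end")
    i = 0
    n = len(read_seq)
    limit = len(template) - start
    while i < n and i < limit and read_seq[i] == template[start + i]:
        i += 1
    return (start + i) - arm.end, read_seq[i:]


def _greedy_len(read_seq: str, template: str, start: int) -> int:
    i = 0
    n = len(read_seq)
    limit = len(template) - start
    while i < n and i < limit and read_seq[i] == template[start + i]:
        i += 1
    return i


def match_read(
    read_seq: str,
    refs: Sequence[MirnaReference],
    max_offset5: int = DEFAULT_MAX_OFFSET5,
    min_core_match: int = DEFAULT_MIN_CORE_MATCH,
    read_id: str = "",
) -> ReadAssignment:
    """Anchor one read against every arm of every reference.

    A (precursor, arm) pair is a candidate when the read matches the
    template ungapped and mismatch-free from its 5' end, starting within
    ±max_offset5 of the arm start, with a templated portion of at least
    ``min_core_match`` nt.  For a given arm the offset with the longest
    templated match wins (ties go to the smaller |offset5|, then to the
    5'-most).  Exactly one candidate arm → assigned; several → ambiguous;
    none → unassigned.  Bad input (empty or non-ACGT/U reads) is recorded
    as unassigned with a reason, never raised.
    """
    seq = str(read_seq).translate(_U2T).upper()
    if not seq:
        return ReadAssignment(read_id, None, UNASSIGNED, 0, reason="empty read")
    if set(seq) - set("ACGT"):
        return ReadAssignment(read_id, None, UNASSIGNED, 0, reason="non-ACGT characters")
    if len(seq) < min_core_match:
        return ReadAssignment(
            read_id, None, UNASSIGNED, 0,
            reason=f"read shorter than min_core_match={min_core_match}",
        )

    candidates: list[tuple[IsomirKey, tuple[int, int]]] = []
    for ref in refs:
        for arm in ref.arms:
            template = ref.extended_template(arm)
            best: Optional[tuple[int, int]] = None  # (templated_len, offset5)
            for off in range(-max_offset5, max_offset5 + 1):
                start = arm.start + off
                if start < 0:
                    continue
                tlen = _greedy_len(seq, template, start)
                if tlen < min_core_match:
                    continue
                if best is None or (tlen, -abs(off), -off) > (
                    best[0], -abs(best[1]), -best[1]
                ):
                    best = (tlen, off)
            if best is None:
                continue
            tlen, off = best
            start = arm.start + off
            key = IsomirKey(
                ref.precursor_id,
                arm.name,
                off,
                (start + tlen) - arm.end,
                seq[tlen:],
            )
            span = (start, min(start + tlen, len(ref.precursor_seq)))
            candidates.append((key, span))

    if not candidates:
        return ReadAssignment(read_id, None, UNASSIGNED, 0, reason="no matching arm")
    if len(candidates) > 1:
        return ReadAssignment(
            read_id, None, AMBIGUOUS, len(candidates),
            candidates=tuple(k for k, _ in candidates),
        )
    key, span = candidates[0]
    return ReadAssignment(read_id, key, ASSIGNED, 1, templated_span=span)


def match_reads(
    reads: Iterable[tuple[str, str]],
    refs: Sequence[MirnaReference],
    max_offset5: int = DEFAULT_MAX_OFFSET5,
    min_core_match: int = DEFAULT_MIN_CORE_MATCH,
) -> Iterable[ReadAssignment]:
    """Match (read_id, sequence) pairs, caching by sequence.

    Small-RNA libraries are highly redundant, so each distinct sequence is
    anchored once and the assignment re-labelled per read.
    """
    cache: dict[str, ReadAssignment] = {}
    for read_id, seq in reads:
        hit = cache.get(seq)
        if hit is None:
            hit = match_read(seq, refs, max_offset5, min_core_match)
            cache[seq] = hit
        yield ReadAssignment(
            read_id, hit.key, hit.status, hit.n_candidate_arms, hit.reason,
            hit.templated_span, hit.candidates,
        )


CANONICAL = "canonical"
TEMPLATED_EXTENDED = "templated_extended"
NT_TAILED = "nt_tailed"
TRIMMED = "trimmed"
SHIFTED = "shifted"


def classify_key(key: IsomirKey) -> str:
    """Coarse isoform class of a key.

    Any 5'-shifted read lands in the ``shifted`` bucket regardless of its
    3' state, because the length-defined species used in ratio work
    (e.g. the 22/23/24-mer series of miR-21-5p) presume a fixed 5' end.
    """
    if key.offset5 != 0:
        return SHIFTED
    if key.tail:
        return NT_TAILED
    if key.delta3_templated > 0:
        return TEMPLATED_EXTENDED
    if key.delta3_templated < 0:
        return TRIMMED
    return CANONICAL


def reconstruct_read(key: IsomirKey, ref: MirnaReference) -> str:
    """Rebuild the read sequence a key describes (inverse of decomposition)."""
    arm = ref.arm(key.arm_name)
    template = ref.extended_template(arm)
    start = arm.start + key.offset5
    end = arm.end + key.delta3_templated
    if start < 0 or end > len(template) or end < start:
        raise ValueError(f"key {key} incompatible with reference template")
    return template[start:end] + key.tail
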
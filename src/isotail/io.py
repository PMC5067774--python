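"""Read input: FASTQ and SAM iteration with per-record fault tolerance.

The pipeline contract is that a malformed read record is skipped and
counted, never fatal on its own; only when more than 10% of records are
malformed does the run abort.  Bio.SeqIO's FASTQ parser raises on the
first bad record, so FASTQ is read here as raw 4-line blocks with
structural validation; well-formed files parse identically to Bio.SeqIO.
SAM goes through pysam.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class ReadStreamStats:
    n_records: int = 0
    n_skipped: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1


def iter_fastq(
    path: str | os.PathLike, stats: Optional[ReadStreamStats] = None
) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file, skipping bad records."""
    stats = stats if stats is not None else ReadStreamStats()
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            if not header.strip():
                continue
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            stats.n_records += 1
            if not qual:
                stats.skip("truncated record")
                break
            header, seq, plus, qual = (
                header.rstrip("\n"), seq.strip(), plus.rstrip("\n"), qual.strip()
            )
            if not header.startswith("@"):
                stats.skip("missing @ header")
                continue
            if not plus.startswith("+"):
                stats.skip("missing + separator")
                continue
            if len(seq) != len(qual):
                stats.skip("sequence/quality length mismatch")
                continue
            if not seq:
                stats.skip("empty sequence")
                continue
            yield header[1:].split()[0], seq


def iter_sam(
    path: str | os.PathLike, stats: Optional[ReadStreamStats] = None
) -> Iterator[tuple[str, str, Optional[tuple[str, int, int]]]]:
    """Yield (read_id, sequence, location) from a SAM file.

    ``location`` is (reference_name, reference_start, reference_end) for
    mapped records and None otherwise; the 3'-end decomposition is always
    recomputed locally from the sequence, the alignment position serves
    only as a region-profiling hint for reads that do not anchor to an
    arm.  Unmapped and sequence-less records are yielded/skipped sanely.
    """
    import pysam

    stats = stats if stats is not None else ReadStreamStats()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            stats.n_records += 1
            if rec.query_sequence is None:
                stats.skip("record without sequence")
                continue
            seq = rec.query_sequence
            if rec.is_unmapped or rec.reference_name is None:
                yield rec.query_name, seq, None
            else:
                yield (
                    rec.query_name,
                    seq,
                    (rec.reference_name, rec.reference_start, rec.reference_end),
                )
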
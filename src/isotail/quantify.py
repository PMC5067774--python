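"""Per-sample isomiR profiles, cpm, tailing/trimming ratios, region counts.

The two statistics at the centre of the analysis are defined on three
length-defined species of one arm, all with the canonical 5' end:

* substrate — the templated-extension isoform (for miR-21-5p, the 23-mer
  "+C" that the non-canonical poly(A) polymerase PAPD5 adenylates),
* tailed — the substrate carrying one extra non-templated A (the 24-mer
  "+CA"),
* trimmed — the canonical-length isoform (the 22-mer), the product of
  PARN trimming back through the tail and the templated extension.

adenylation_ratio = tailed / substrate and degradation_ratio =
trimmed / substrate.  Both are undefined (None, not zero) when the
substrate count is zero, and both are invariant under rescaling of all
counts — so they are identical whether computed from raw counts or cpm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .isomir import (
    AMBIGUOUS,
    ASSIGNED,
    UNASSIGNED,
    IsomirKey,
    ReadAssignment,
)
from .reference import MirnaReference, PrecursorRegions

logger = logging.getLogger(__name__)

OUTSIDE = "outside"


@dataclass
class IsomirProfile:
    """Counts per isomiR species for one sample, plus a QC tally."""

    sample_id: str
    counts: dict[IsomirKey, float] = field(default_factory=dict)
    qc: dict[str, float] = field(default_factory=dict)
    library_size_for_cpm: Optional[float] = None

    @property
    def total_counted(self) -> float:
        return float(sum(self.counts.values()))


def aggregate(
    assignments: Iterable[ReadAssignment],
    sample_id: str,
    include_ambiguous: bool = False,
) -> IsomirProfile:
    """Tally assignments into an isomiR profile.

    Ambiguous reads (matching more than one arm) are excluded from the
    counts by default and tallied in QC; with ``include_ambiguous`` each
    candidate key instead receives fractional weight 1/n.  Unassigned
    reads are tallied in QC by reason.
    """
    profile = IsomirProfile(sample_id)
    qc = profile.qc
    qc.update({"assigned": 0.0, "ambiguous": 0.0, "unassigned": 0.0})
    counts = profile.counts
    for a in assignments:
        if a.status == ASSIGNED:
            counts[a.key] = counts.get(a.key, 0.0) + 1.0
            qc["assigned"] += 1
        elif a.status == AMBIGUOUS:
            qc["ambiguous"] += 1
            if include_ambiguous and a.candidates:
                w = 1.0 / len(a.candidates)
                for key in a.candidates:
                    counts[key] = counts.get(key, 0.0) + w
        else:
            qc["unassigned"] += 1
            if a.reason:
                k = f"unassigned:{a.reason}"
                qc[k] = qc.get(k, 0.0) + 1
    return profile


def aggregate_counts(
    keyed_counts: Mapping[IsomirKey, float],
    sample_id: str,
    qc: Optional[Mapping[str, float]] = None,
) -> IsomirProfile:
    """Build a profile directly from pre-tallied per-key counts."""
    profile = IsomirProfile(sample_id, dict(keyed_counts))
    if qc:
        profile.qc.update(qc)
    return profile


def cpm(
    profile: IsomirProfile, denominator: str | float = "counted"
) -> dict[IsomirKey, float]:
    """Counts per million over the chosen library-size denominator.

    denominator='counted' uses the profile's own assigned total (so the
    cpm values sum to 1e6); a number uses that library size instead; the
    string 'supplied' uses ``profile.library_size_for_cpm``.
    """
    if denominator == "counted":
        denom = profile.total_counted
    elif denominator == "supplied":
        denom = profile.library_size_for_cpm
        if denom is None:
            raise ValueError("profile has no supplied library size")
    else:
        denom = float(denominator)
    if not denom or denom <= 0:
        raise ValueError(f"cpm denominator must be positive, got {denom}")
    scale = 1e6 / denom
    return {k: v * scale for k, v in profile.counts.items()}


@dataclass
class RatioResult:
    """Adenylation and degradation ratios for one arm, with their counts."""

    precursor_id: str
    arm_name: str
    substrate_count: float
    tailed_count: float
    trimmed_count: float
    adenylation_ratio: Optional[float]
    degradation_ratio: Optional[float]


def tailing_ratios(
    profile: IsomirProfile,
    precursor_id: str,
    arm_name: str,
    substrate_delta3: int = 1,
    tail_nt: str = "A",
) -> RatioResult:
    """Compute the adenylation and degradation ratios for one arm.

    Only reads with the canonical 5' end (offset5=0) enter the three
    species.  The tailed species is the substrate plus exactly one
    non-templated ``tail_nt``; longer tails are reported in the profile
    but excluded here.  The trimmed species is exactly the
    canonical-length isoform, not the sum of all shorter isoforms.
    Zero substrate → both ratios None (missing, never 0).
    """
    sub_key = IsomirKey(precursor_id, arm_name, 0, substrate_delta3, "")
    tail_key = IsomirKey(precursor_id, arm_name, 0, substrate_delta3, tail_nt)
    trim_key = IsomirKey(precursor_id, arm_name, 0, 0, "")
    sub = profile.counts.get(sub_key, 0.0)
    tailed = profile.counts.get(tail_key, 0.0)
    trimmed = profile.counts.get(trim_key, 0.0)
    if sub > 0:
        aden: Optional[float] = tailed / sub
        degr: Optional[float] = trimmed / sub
    else:
        aden = degr = None
        logger.warning(
            "sample %s: substrate species (delta3=%+d) absent for %s/%s; "
            "ratios undefined",
            profile.sample_id, substrate_delta3, precursor_id, arm_name,
        )
    return RatioResult(precursor_id, arm_name, sub, tailed, trimmed, aden, degr)


@dataclass
class RegionProfile:
    """Read counts per precursor sub-region for one sample."""

    sample_id: str
    precursor_id: str
    counts: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))


def assign_region(
    interval: tuple[int, int], regions: PrecursorRegions
) -> str:
    """Majority-overlap region for one read interval; ties → 5'-most region."""
    best_name = OUTSIDE
    best_ov = 0
    for name, (lo, hi) in regions.items():
        ov = min(interval[1], hi) - max(interval[0], lo)
        if ov > best_ov:  # strict: first (5'-most) region wins ties
            best_ov = ov
            best_name = name
    return best_name


def region_counts(
    intervals: Iterable[Optional[tuple[int, int]]],
    regions: PrecursorRegions,
    sample_id: str = "",
    precursor_id: str = "",
    weights: Optional[Iterable[float]] = None,
) -> RegionProfile:
    """Count located reads per precursor region by majority overlap.

    Each read contributes to the region holding the majority of its
    precursor-aligned bases; ties go to the 5'-most tied region; reads
    overlapping no region land in an 'outside' bucket.  A None interval
    (read not locatable on the precursor) also counts as outside.
    """
    profile = RegionProfile(sample_id, precursor_id)
    counts = profile.counts
    for name in PrecursorRegions.ORDER:
        counts[name] = 0.0
    counts[OUTSIDE] = 0.0
    if weights is None:
        for iv in intervals:
            counts[assign_region(iv, regions) if iv else OUTSIDE] += 1.0
    else:
        for iv, w in zip(intervals, weights):
            counts[assign_region(iv, regions) if iv else OUTSIDE] += w
    return profile


def locate_read(read_seq: str, ref: MirnaReference) -> Optional[tuple[int, int]]:
    """Locate a read on the precursor by exact substring search.

    Used for reads that did not anchor to a mature arm (loop and flank
    fragments).  Returns the first-occurrence interval or None.
    """
    pos = ref.precursor_seq.find(read_seq)
    if pos < 0:
        return None
    return (pos, pos + len(read_seq))
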
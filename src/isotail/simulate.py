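"""Kinetic simulator for small-RNA libraries under tailing-and-trimming.

The turnover model is a minimal linear chain of three species of one
mature arm, motivated by the PAPD5/PARN pathway: Dicer releases the
*substrate* isoform (carrying a one-nucleotide templated extension, the
"+C" species for miR-21-5p) at rate ``alpha``; a non-canonical poly(A)
polymerase (PAPD5) adds a single non-templated adenosine at rate
``a_rate`` giving the *tailed* species; a 3'-to-5' exonuclease (PARN)
trims the tailed species back to the *trimmed*, canonical-length isoform
at rate ``t_rate``; every species additionally decays at the basal rate
``delta``.  At steady state

    S_sub  = alpha / (a_rate + delta)
    S_tail = a_rate * S_sub / (t_rate + delta)
    S_trim = t_rate * S_tail / delta

so the expected adenylation ratio is a_rate / (t_rate + delta) and the
expected degradation ratio is (t_rate / delta) * a_rate / (t_rate + delta)
— both independent of the production rate alpha.  This linear chain is a
modelling choice of this package: the pathway direction it encodes
(higher PAPD5/PARN activity → higher both ratios, lower substrate level)
is what the downstream statistics are tested against.

A sequencing library is drawn multinomially from the steady-state
proportions, optionally mixed with a background of loop/3p-arm/flank
fragments (so precursor-region profiling has signal), and per-base
substitution noise is applied.  Output is deterministic for a fixed
seed; per-sample seeds are derived from the root seed and sample index.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, TextIO

import numpy as np

from .reference import MatureArm, MirnaReference, derive_regions

_OTHER = {
    "A": np.frombuffer(b"CGT", dtype="S1"),
    "C": np.frombuffer(b"AGT", dtype="S1"),
    "G": np.frombuffer(b"ACT", dtype="S1"),
    "T": np.frombuffer(b"ACG", dtype="S1"),
}

#: fixed demo precursor: 20 nt upstream flank, 22 nt 5p arm, 16 nt loop,
#: 22 nt 3p arm, 20 nt downstream flank; every 14-mer occurs once, the
#: template base after the 5p arm is C and the next one is not A, so the
#: substrate (+C), tailed (+CA) and trimmed species are all well defined.
DEMO_PRECURSOR_SEQ = (
    "GAGAGCGCTCAGATACTACTATTGGACATTACGGCCCGGCCCCCAACATCCCAGCGGCATTGCTTAATTCCTTACGTCTCGACCGACCAGTTTGCTTAAA"
)


def demo_reference(precursor_id: str = "mir-sim-1") -> MirnaReference:
    """The synthetic two-arm precursor used throughout examples and tests."""
    return MirnaReference(
        precursor_id,
        DEMO_PRECURSOR_SEQ,
        (
            MatureArm("miR-sim-5p", 20, 42),
            MatureArm("miR-sim-3p", 58, 80),
        ),
    )


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated tailing-and-trimming experiment.

    Rates are in arbitrary inverse-time units; only their ratios matter
    for the steady-state composition.  ``group_effects`` maps a group
    label to multiplicative factors on 'alpha', 'a_rate' and/or 't_rate'
    (e.g. {"control": {}, "aso": {"a_rate": 1.5, "t_rate": 1.5}}).
    """

    reference: MirnaReference = field(default_factory=demo_reference)
    arm_name: str = "5p"
    alpha: float = 100.0        # substrate production (Dicer output)
    a_rate: float = 0.2         # adenylation, PAPD5 arm of the pathway
    t_rate: float = 0.3         # trimming, PARN arm of the pathway
    delta: float = 0.1          # basal decay of every species
    substrate_delta3: int = 1   # templated extension of the substrate (+C)
    tail_nt: str = "A"
    seq_error: float = 0.001    # per-base substitution probability
    depth: int = 100_000        # reads per sample
    n_samples: int = 3          # samples per group (biological replicates)
    background_fraction: float = 0.2  # loop/3p/flank fragment reads
    group_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"control": {}}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "a_rate", "t_rate", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.seq_error <= 0.05:
            raise ValueError("seq_error must lie in [0, 0.05]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")

    def with_effects(self, effects: Mapping[str, float]) -> "SimScenario":
        """Scenario with group-effect multipliers folded into the rates."""
        return replace(
            self,
            alpha=self.alpha * effects.get("alpha", 1.0),
            a_rate=self.a_rate * effects.get("a_rate", 1.0),
            t_rate=self.t_rate * effects.get("t_rate", 1.0),
        )


@dataclass(frozen=True)
class SimTruth:
    """Closed-form steady state of the three-species chain."""

    s_sub: float
    s_tail: float
    s_trim: float
    adenylation_ratio: float
    degradation_ratio: float


def steady_state(scn: SimScenario) -> SimTruth:
    """Solve the linear balance equations of the chain analytically."""
    s_sub = scn.alpha / (scn.a_rate + scn.delta)
    s_tail = scn.a_rate * s_sub / (scn.t_rate + scn.delta)
    s_trim = scn.t_rate * s_tail / scn.delta
    return SimTruth(
        s_sub=s_sub,
        s_tail=s_tail,
        s_trim=s_trim,
        adenylation_ratio=s_tail / s_sub,
        degradation_ratio=s_trim / s_sub,
    )


def _species_sequences(scn: SimScenario) -> dict[str, str]:
    """Read sequence of each simulated species (DNA alphabet)."""
    ref = scn.reference
    arm = ref.arm(scn.arm_name)
    template = ref.extended_template(arm)
    canonical = template[arm.start : arm.end]
    substrate = template[arm.start : arm.end + scn.substrate_delta3]
    species = {
        "substrate": substrate,
        "tailed": substrate + scn.tail_nt,
        "trimmed": canonical,
    }
    if scn.background_fraction > 0:
        regions = derive_regions(ref)
        measured_region = "mature_3p" if arm.side == "3p" else "mature_5p"
        for name, (lo, hi) in regions.items():
            if name == measured_region:
                continue
            species[f"bg:{name}"] = ref.precursor_seq[lo:hi]
    return species


def _species_proportions(scn: SimScenario) -> tuple[list[str], np.ndarray]:
    truth = steady_state(scn)
    mature = np.array([truth.s_sub, truth.s_tail, truth.s_trim], float)
    mature = mature / mature.sum() * (1.0 - scn.background_fraction)
    names = ["substrate", "tailed", "trimmed"]
    seqs = _species_sequences(scn)
    bg_names = [n for n in seqs if n.startswith("bg:")]
    props = list(mature)
    if bg_names:
        share = scn.background_fraction / len(bg_names)
        for n in bg_names:
            names.append(n)
            props.append(share)
    p = np.array(props, float)
    return names, p / p.sum()


def _mutate_counts(
    seq: str, k: int, error: float, rng: np.random.Generator
) -> list[str]:
    """Draw k error-bearing copies of ``seq`` (each with >=1 substitution).

    The number of substitutions per copy follows Binomial(L, error)
    conditioned on being >=1; positions are uniform without replacement;
    the substituted base is uniform over the three alternatives.
    """
    L = len(seq)
    m_support = np.arange(1, L + 1)
    logpmf = (
        np.log(np.array([math.comb(L, int(m)) for m in m_support], float))
        + m_support * math.log(error)
        + (L - m_support) * math.log1p(-error)
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    ms = rng.choice(m_support, size=k, p=pmf)
    base = np.frombuffer(seq.encode(), dtype="S1")
    out = []
    for m in ms:
        arr = base.copy()
        pos = rng.choice(L, size=int(m), replace=False)
        for j in pos:
            orig = arr[j].decode()
            arr[j] = rng.choice(_OTHER[orig])
        out.append(arr.tobytes().decode())
    return out


@dataclass
class SampleReads:
    """One simulated library: collapsed read counts plus its ground truth."""

    sample_id: str
    group: str
    sequence_counts: dict[str, int]
    species_counts: dict[str, int]
    truth: SimTruth

    @property
    def depth(self) -> int:
        return sum(self.sequence_counts.values())

    def reads(self):
        """Yield (read_id, sequence) pairs in deterministic order."""
        i = 0
        for seq, n in self.sequence_counts.items():
            for _ in range(n):
                i += 1
                yield f"{self.sample_id}.r{i:07d}", seq

    def write_fastq(self, path_or_handle: str | os.PathLike | TextIO) -> None:
        """Write a plain 4-line FASTQ with constant quality."""
        if hasattr(path_or_handle, "write"):
            self._write(path_or_handle)
        else:
            with open(path_or_handle, "w") as fh:
                self._write(fh)

    def _write(self, fh: TextIO) -> None:
        for rid, seq in self.reads():
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_sample(
    scn: SimScenario, sample_seed: int, sample_id: str = "sample", group: str = ""
) -> SampleReads:
    """Draw one library of ``scn.depth`` reads from the steady state.

    Species counts are multinomial in the steady-state proportions; the
    number of error-bearing copies of each species is binomial in the
    per-read error probability 1-(1-e)^L, and those copies get explicit
    substitution patterns.  Deterministic for a fixed (scenario, seed).
    """
    rng = np.random.default_rng(sample_seed)
    names, props = _species_proportions(scn)
    seqs = _species_sequences(scn)
    counts = rng.multinomial(scn.depth, props)
    species_counts = {n: int(c) for n, c in zip(names, counts)}
    collapsed: dict[str, int] = {}
    for name, n in species_counts.items():
        if n == 0:
            continue
        seq = seqs[name]
        if scn.seq_error > 0:
            p_err = 1.0 - (1.0 - scn.seq_error) ** len(seq)
            k = int(rng.binomial(n, p_err))
        else:
            k = 0
        if n - k > 0:
            collapsed[seq] = collapsed.get(seq, 0) + (n - k)
        for mutant in _mutate_counts(seq, k, scn.seq_error, rng) if k else ():
            collapsed[mutant] = collapsed.get(mutant, 0) + 1
    return SampleReads(sample_id, group, collapsed, species_counts, steady_state(scn))


def sample_seed(root_seed: int, index: int) -> int:
    """Deterministic per-sample seed derived from the root seed."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class ExperimentResult:
    """All samples of a multi-group simulated experiment."""

    samples: list[SampleReads]
    truth_by_group: dict[str, SimTruth]
    scenario: SimScenario

    @property
    def metadata(self) -> dict[str, str]:
        return {s.sample_id: s.group for s in self.samples}


def simulate_experiment(
    scn: SimScenario, outdir: Optional[str | os.PathLike] = None
) -> ExperimentResult:
    """Simulate every group of a scenario; optionally write files.

    Group effects multiply the rates before the steady state is solved.
    With ``outdir`` given, writes one FASTQ per sample, a samples.tsv
    metadata sheet (sample_id, group, fastq) and a truth.json with the
    per-group closed-form expectations.
    """
    samples: list[SampleReads] = []
    truth_by_group: dict[str, SimTruth] = {}
    index = 0
    for group, effects in scn.group_effects.items():
        g_scn = scn.with_effects(effects)
        truth_by_group[group] = steady_state(g_scn)
        for rep in range(scn.n_samples):
            sid = f"{group}_{rep + 1}"
            samples.append(
                simulate_sample(g_scn, sample_seed(scn.seed, index), sid, group)
            )
            index += 1
    result = ExperimentResult(samples, truth_by_group, scn)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "samples.tsv", "w") as fh:
            fh.write("sample_id\tgroup\tfastq\n")
            for s in samples:
                fq = outdir / f"{s.sample_id}.fastq"
                s.write_fastq(fq)
                fh.write(f"{s.sample_id}\t{s.group}\t{fq.name}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    g: {
                        "s_sub": t.s_sub,
                        "s_tail": t.s_tail,
                        "s_trim": t.s_trim,
                        "adenylation_ratio": t.adenylation_ratio,
                        "degradation_ratio": t.degradation_ratio,
                    }
                    for g, t in truth_by_group.items()
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
    return result


def fraction_series_scenario(
    base: SimScenario, a_rates: Sequence[float]
) -> SimScenario:
    """Scenario whose groups are pseudo-fractions with increasing a_rate.

    Emulates a size-fractionation series in which the adenylation
    activity varies across fractions while trimming and decay stay put.
    """
    effects = {
        f"fraction_{i + 1}": {"a_rate": a / base.a_rate}
        for i, a in enumerate(a_rates)
    }
    return replace(base, group_effects=effects)
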
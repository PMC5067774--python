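"""Validation harness: property checks of the pipeline on known ground truth.

Each function here sets up a self-contained experiment — randomised toy
references, simulated libraries with known kinetics, null comparisons —
runs the package's own code path on it, and returns plain measured
numbers.  The decomposition check carries its own brute-force
enumeration oracle so that the greedy implementation is compared against
an independent reference answer, not against itself.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .isomir import decompose_3prime
from .pipeline import RunConfig, quantify_sequences, run_quantify
from .quantify import IsomirProfile, tailing_ratios
from .isomir import IsomirKey
from .reference import MatureArm, MirnaReference, write_reference
from .simulate import SimScenario, sample_seed, simulate_experiment, simulate_sample
from .stats import compare_groups


def _subseed(root_seed: int, label: int) -> int:
    state = np.random.SeedSequence(entropy=root_seed, spawn_key=(label,))
    return int(state.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# 3'-end decomposition vs brute force


def _brute_force_decompose(
    read: str, template: str, arm_start: int, arm_end: int, offset5: int
) -> tuple[int, str]:
    """Enumerate every (templated prefix, tail) split of the read and keep
    the longest feasible templated prefix."""
    start = arm_start + offset5
    best = 0
    for tlen in range(len(read) + 1):
        if start + tlen <= len(template) and read[:tlen] == template[start : start + tlen]:
            best = tlen
    return (start + best) - arm_end, read[best:]


def check_decomposition_oracle(
    seed: int, n_refs: int = 20, reads_per_ref: int = 60
) -> dict:
    """Fraction of randomised reads on which greedy decomposition agrees
    with the brute-force split enumeration (expected: 1.0)."""
    rng = np.random.default_rng(_subseed(seed, 1))
    n_total = n_agree = 0
    for r in range(n_refs):
        n = int(rng.integers(60, 90))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        arm_len = int(rng.integers(16, 26))
        start = int(rng.integers(3, n - arm_len - 12))
        ref = MirnaReference(
            f"toy-{r}", seq, (MatureArm(f"toy-{r}-5p", start, start + arm_len),)
        )
        (arm,) = ref.arms
        template = ref.extended_template(arm)
        for _ in range(reads_per_ref):
            offset5 = int(rng.integers(-2, 3))
            s = arm.start + offset5
            core = int(rng.integers(14, arm.canonical_length - 1))
            templated_extra = int(rng.integers(0, 5))
            read = template[s : s + core + templated_extra]
            read += "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 4))))
            got = decompose_3prime(read, ref, arm, offset5)
            want = _brute_force_decompose(read, template, arm.start, arm.end, offset5)
            n_total += 1
            n_agree += got == want
    return {"agreement_fraction": n_agree / n_total, "n": n_total}


# ---------------------------------------------------------------------------
# ratio arithmetic


def check_ratio_arithmetic() -> dict:
    """The worked count example {canonical: 20, +C: 40, +CA: 10} and its
    invariance under count rescaling."""
    def ratios(scale: float):
        profile = IsomirProfile("s", {
            IsomirKey("p", "a", 0, 0, ""): 20 * scale,
            IsomirKey("p", "a", 0, 1, ""): 40 * scale,
            IsomirKey("p", "a", 0, 1, "A"): 10 * scale,
        })
        res = tailing_ratios(profile, "p", "a")
        return res.adenylation_ratio, res.degradation_ratio

    aden, degr = ratios(1.0)
    aden_s, degr_s = ratios(37.5)
    return {
        "adenylation_ratio": aden,
        "degradation_ratio": degr,
        "scale_invariant": float(aden == aden_s and degr == degr_s),
        "n": 70,
    }


# ---------------------------------------------------------------------------
# simulation-based checks


def _estimate_ratios(scn: SimScenario, seed: int) -> tuple[Optional[float], Optional[float], dict, float]:
    """Simulate one library and push it through quantification; returns
    (adenylation, degradation, region counts, substrate cpm) for the 5p arm."""
    sample = simulate_sample(scn, seed, "s")
    res = quantify_sequences(sample.sequence_counts, [scn.reference], "s")
    arm = scn.reference.arm(scn.arm_name)
    ratio = next(r for r in res.ratios if r.arm_name == arm.name)
    regions = next(
        r for r in res.regions if r.precursor_id == scn.reference.precursor_id
    )
    total = res.profile.total_counted
    sub_cpm = ratio.substrate_count * 1e6 / total if total else float("nan")
    return ratio.adenylation_ratio, ratio.degradation_ratio, dict(regions.counts), sub_cpm


def check_closed_form_recovery(seed: int, n_seeds: int = 10, depth: int = 100_000) -> dict:
    """Mean pipeline-estimated ratios over replicate libraries of the
    worked kinetic scenario, run end-to-end through FASTQ files, with the
    binomial (delta-method) standard errors of those means.  Closed form:
    0.5 and 1.5."""
    scn = SimScenario(
        alpha=100, a_rate=0.2, t_rate=0.3, delta=0.1,
        seq_error=0.0, depth=depth, n_samples=n_seeds,
        group_effects={"g": {}}, seed=_subseed(seed, 3),
    )
    with tempfile.TemporaryDirectory() as tmp:
        simdir = Path(tmp) / "sim"
        simulate_experiment(scn, simdir)
        write_reference([scn.reference], simdir / "reference.fasta",
                        simdir / "reference.tsv")
        config = RunConfig(
            reference_fasta=str(simdir / "reference.fasta"),
            annotation=str(simdir / "reference.tsv"),
            samples_tsv=str(simdir / "samples.tsv"),
            outdir=str(Path(tmp) / "out"),
        )
        run_quantify(config)
        ratios = pd.read_csv(Path(tmp) / "out" / "ratios.tsv", sep="\t")
    arm = scn.reference.arm(scn.arm_name)
    five = ratios[ratios["arm_name"] == arm.name]
    aden = five["adenylation_ratio"].to_numpy(float)
    degr = five["degradation_ratio"].to_numpy(float)
    sub = five["substrate_count"].to_numpy(float)
    tail = five["tailed_count"].to_numpy(float)
    trim = five["trimmed_count"].to_numpy(float)
    k = len(aden)
    # delta-method (binomial) sampling variance of each count ratio:
    # Var(T/S) ~= (T/S)^2 (1/T + 1/S) under multinomial sampling
    se_aden = np.sqrt((aden**2 * (1 / tail + 1 / sub)).sum()) / k
    se_degr = np.sqrt((degr**2 * (1 / trim + 1 / sub)).sum()) / k
    return {
        "adenylation_mean": float(aden.mean()),
        "adenylation_se": float(se_aden),
        "degradation_mean": float(degr.mean()),
        "degradation_se": float(se_degr),
        "n": k * depth,
    }


def check_aso_direction(seed: int, n_pairs: int = 100, depth: int = 100_000) -> dict:
    """Jointly de-repressing both enzymatic steps (a_rate and t_rate x1.5,
    the ASO-experiment direction) should raise both estimated ratios and
    lower the substrate cpm in nearly every replicate pair."""
    base = SimScenario(depth=depth, seed=0)
    up = SimScenario(a_rate=base.a_rate * 1.5, t_rate=base.t_rate * 1.5,
                     depth=depth, seed=0)
    root = _subseed(seed, 4)
    n_both_up = n_sub_down = 0
    for i in range(n_pairs):
        a0, d0, _, cpm0 = _estimate_ratios(base, sample_seed(root, 2 * i))
        a1, d1, _, cpm1 = _estimate_ratios(up, sample_seed(root, 2 * i + 1))
        n_both_up += (a1 > a0) and (d1 > d0)
        n_sub_down += cpm1 < cpm0
    return {
        "fraction_both_ratios_increase": n_both_up / n_pairs,
        "fraction_substrate_cpm_decreases": n_sub_down / n_pairs,
        "n": n_pairs,
    }


def check_type_one_error(
    seed: int, n_replicates: int = 100, n_per_group: int = 3, alpha: float = 0.05
) -> dict:
    """Two groups simulated with identical rates: the raw Student t-test
    on per-sample adenylation ratios should reject at ~alpha."""
    scn = SimScenario()
    root = _subseed(seed, 5)
    n_reject = n_tested = 0
    metadata = {f"a{i}": "g1" for i in range(n_per_group)}
    metadata.update({f"b{i}": "g2" for i in range(n_per_group)})
    for rep in range(n_replicates):
        rows = []
        for j, sid in enumerate(metadata):
            aden, _, _, _ = _estimate_ratios(
                scn, sample_seed(root, rep * len(metadata) + j)
            )
            rows.append({"sample_id": sid, "precursor_id": "p", "arm_name": "a",
                         "metric": "adenylation_ratio", "value": aden})
        (comp,) = compare_groups(pd.DataFrame(rows), metadata, ("g1", "g2"))
        if not comp.skipped:
            n_tested += 1
            n_reject += comp.p_value < alpha
    return {
        "rejection_fraction": n_reject / n_tested,
        "n": n_tested,
    }


def check_processing_proxy(seed: int, n_pairs: int = 10, depth: int = 100_000) -> dict:
    """Doubling the tailing/trimming rates must shift the mature substrate
    while leaving loop/3p-arm/flank fragment counts statistically flat.

    Returns the largest |z| across background regions (paired totals,
    Poisson-scale z = diff / sqrt(sum)) and the mean substrate cpm under
    both conditions."""
    base = SimScenario(depth=depth, seed=0)
    mod = SimScenario(a_rate=base.a_rate * 2, t_rate=base.t_rate * 2,
                      depth=depth, seed=0)
    root = _subseed(seed, 6)
    bg_regions = ["upstream_of_5p", "loop", "mature_3p", "downstream_of_3p"]
    totals0 = {r: 0.0 for r in bg_regions}
    totals1 = {r: 0.0 for r in bg_regions}
    cpm0s, cpm1s = [], []
    for i in range(n_pairs):
        _, _, reg0, cpm0 = _estimate_ratios(base, sample_seed(root, 2 * i))
        _, _, reg1, cpm1 = _estimate_ratios(mod, sample_seed(root, 2 * i + 1))
        for r in bg_regions:
            totals0[r] += reg0.get(r, 0.0)
            totals1[r] += reg1.get(r, 0.0)
        cpm0s.append(cpm0)
        cpm1s.append(cpm1)
    z_max = max(
        abs(totals1[r] - totals0[r]) / np.sqrt(totals1[r] + totals0[r])
        for r in bg_regions
    )
    return {
        "max_background_z": float(z_max),
        "substrate_cpm_base": float(np.mean(cpm0s)),
        "substrate_cpm_modulated": float(np.mean(cpm1s)),
        "n": 2 * n_pairs * depth,
    }


def check_determinism(seed: int, depth: int = 20_000) -> dict:
    """Two runs from the same seed and inputs must be byte-identical:
    the FASTQ files and every result table."""
    scn = SimScenario(
        depth=depth, n_samples=2, seed=_subseed(seed, 7),
        group_effects={"control": {}, "aso": {"a_rate": 1.5, "t_rate": 1.5}},
    )
    identical = True
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        blobs = []
        for run in ("run1", "run2"):
            simdir = tmp / run / "sim"
            simulate_experiment(scn, simdir)
            write_reference([scn.reference], simdir / "reference.fasta",
                            simdir / "reference.tsv")
            config = RunConfig(
                reference_fasta=str(simdir / "reference.fasta"),
                annotation=str(simdir / "reference.tsv"),
                samples_tsv=str(simdir / "samples.tsv"),
                outdir=str(tmp / run / "out"),
            )
            run_quantify(config)
            blob = {}
            for f in sorted(simdir.glob("*.fastq")):
                blob[f.name] = f.read_bytes()
            for f in sorted((tmp / run / "out").glob("*.tsv")):
                blob[f.name] = f.read_bytes()
            blobs.append(blob)
        identical = blobs[0] == blobs[1]
    return {"identical": float(identical), "n": len(blobs[0])}
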
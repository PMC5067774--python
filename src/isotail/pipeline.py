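"""End-to-end runs: simulate, quantify, compare — with tabular outputs.

Each stage is a plain function over library objects; the file-facing
wrappers (`run_simulate`, `run_quantify`, `run_compare`) add config
handling, TSV/JSON output and a run manifest.  Outputs are deterministic
for fixed inputs: tables are sorted, and the only timestamp lives in the
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .io import ReadStreamStats, iter_fastq, iter_sam
from .isomir import (
    AMBIGUOUS,
    ASSIGNED,
    DEFAULT_MAX_OFFSET5,
    DEFAULT_MIN_CORE_MATCH,
    classify_key,
    match_read,
)
from .quantify import (
    IsomirProfile,
    RatioResult,
    RegionProfile,
    aggregate_counts,
    cpm,
    locate_read,
    region_counts,
    tailing_ratios,
)
from .reference import MirnaReference, derive_regions, load_reference
from .simulate import SimScenario, simulate_experiment
from .stats import comparisons_to_frame, compare_groups

logger = logging.getLogger(__name__)

MAX_SKIP_FRACTION = 0.10


@dataclass
class RunConfig:
    """Settings for a pipeline run; mirrors the CLI flags and YAML config."""

    reference_fasta: Optional[str] = None
    annotation: Optional[str] = None
    annotation_dialect: str = "tsv"
    samples_tsv: Optional[str] = None     # sample_id, fastq-or-sam [, group]
    metadata_tsv: Optional[str] = None    # defaults to samples_tsv
    outdir: str = "isotail_out"
    max_offset5: int = DEFAULT_MAX_OFFSET5
    min_core_match: int = DEFAULT_MIN_CORE_MATCH
    substrate_delta3: int = 1
    tail_nt: str = "A"
    include_ambiguous: bool = False
    contrast: Optional[tuple[str, str]] = None
    adjust: str = "none"
    welch: bool = False
    log_level: str = "INFO"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # SimScenario overrides

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if data.get("contrast") is not None:
            data["contrast"] = tuple(data["contrast"])
        return cls(**data)

    def validate_paths(self, need: Sequence[str]) -> None:
        for name in need:
            value = getattr(self, name)
            if value is None:
                raise FileNotFoundError(f"config field {name!r} is required")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value!r}")


@dataclass
class SampleResult:
    """All per-sample outputs of the quantify stage."""

    sample_id: str
    profile: IsomirProfile
    ratios: list[RatioResult]
    regions: list[RegionProfile]
    qc: dict[str, float]


def quantify_sequences(
    seq_counts: Mapping[str, float],
    refs: Sequence[MirnaReference],
    sample_id: str,
    max_offset5: int = DEFAULT_MAX_OFFSET5,
    min_core_match: int = DEFAULT_MIN_CORE_MATCH,
    substrate_delta3: int = 1,
    tail_nt: str = "A",
    include_ambiguous: bool = False,
    location_hints: Optional[Mapping[str, tuple[str, int, int]]] = None,
) -> SampleResult:
    """Quantify one sample given collapsed sequence counts.

    Each distinct sequence is anchored once.  Assigned reads enter the
    isomiR profile keyed by species; every read that can be located on a
    precursor (via its arm anchor, an exact substring hit, or a supplied
    alignment hint) enters the region profile of that precursor.
    """
    keyed: dict = {}
    qc = {"assigned": 0.0, "ambiguous": 0.0, "unassigned": 0.0}
    located: dict[str, tuple[list, list]] = {
        ref.precursor_id: ([], []) for ref in refs
    }
    by_id = {ref.precursor_id: ref for ref in refs}
    for seq, n in seq_counts.items():
        n = float(n)
        a = match_read(seq, refs, max_offset5, min_core_match)
        if a.status == ASSIGNED:
            keyed[a.key] = keyed.get(a.key, 0.0) + n
            qc["assigned"] += n
            ivs, ws = located[a.key.precursor_id]
            ivs.append(a.templated_span)
            ws.append(n)
            continue
        if a.status == AMBIGUOUS:
            qc["ambiguous"] += n
            if include_ambiguous and a.candidates:
                w = n / len(a.candidates)
                for key in a.candidates:
                    keyed[key] = keyed.get(key, 0.0) + w
            continue
        qc["unassigned"] += n
        if a.reason:
            k = f"unassigned:{a.reason}"
            qc[k] = qc.get(k, 0.0) + n
        placed = False
        hint = location_hints.get(seq) if location_hints else None
        if hint is not None and hint[0] in located:
            ivs, ws = located[hint[0]]
            ivs.append((hint[1], hint[2]))
            ws.append(n)
            placed = True
        if not placed:
            for ref in refs:
                iv = locate_read(seq, ref)
                if iv is not None:
                    ivs, ws = located[ref.precursor_id]
                    ivs.append(iv)
                    ws.append(n)
                    break

    profile = aggregate_counts(keyed, sample_id, qc)
    ratios = []
    regions = []
    for ref in refs:
        for arm in ref.arms:
            ratios.append(
                tailing_ratios(profile, ref.precursor_id, arm.name,
                               substrate_delta3, tail_nt)
            )
        ivs, ws = located[ref.precursor_id]
        regions.append(
            region_counts(ivs, derive_regions(ref), sample_id,
                          ref.precursor_id, weights=ws)
        )
    return SampleResult(sample_id, profile, ratios, regions, qc)


def quantify_reads(
    reads: Iterable[tuple[str, str]],
    refs: Sequence[MirnaReference],
    sample_id: str,
    **kwargs,
) -> SampleResult:
    """Quantify one sample from a (read_id, sequence) stream."""
    counts: dict[str, int] = {}
    for _, seq in reads:
        counts[seq] = counts.get(seq, 0) + 1
    return quantify_sequences(counts, refs, sample_id, **kwargs)


# ---------------------------------------------------------------------------
# tables


def profile_frame(result: SampleResult) -> pd.DataFrame:
    """Per-species table: one row per isomiR key with count and cpm."""
    rows = []
    profile = result.profile
    cpms = cpm(profile) if profile.total_counted > 0 else {}
    for key in sorted(profile.counts):
        rows.append({
            "sample_id": profile.sample_id,
            "precursor_id": key.precursor_id,
            "arm_name": key.arm_name,
            "offset5": key.offset5,
            "delta3_templated": key.delta3_templated,
            "tail": key.tail,
            "isoform_class": classify_key(key),
            "count": profile.counts[key],
            "cpm": cpms.get(key, 0.0),
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "precursor_id", "arm_name", "offset5",
        "delta3_templated", "tail", "isoform_class", "count", "cpm",
    ])


def ratio_frame(results: Sequence[SampleResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for r in res.ratios:
            rows.append({
                "sample_id": res.sample_id,
                "precursor_id": r.precursor_id,
                "arm_name": r.arm_name,
                "substrate_count": r.substrate_count,
                "tailed_count": r.tailed_count,
                "trimmed_count": r.trimmed_count,
                "adenylation_ratio": r.adenylation_ratio,
                "degradation_ratio": r.degradation_ratio,
            })
    return pd.DataFrame(rows)


def region_frame(results: Sequence[SampleResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for reg in res.regions:
            for region, count in sorted(reg.counts.items()):
                rows.append({
                    "sample_id": res.sample_id,
                    "precursor_id": reg.precursor_id,
                    "region": region,
                    "count": count,
                })
    return pd.DataFrame(rows)


def qc_frame(results: Sequence[SampleResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for k, v in sorted(res.qc.items()):
            rows.append({"sample_id": res.sample_id, "category": k, "count": v})
    return pd.DataFrame(rows)


def metric_table(results: Sequence[SampleResult]) -> pd.DataFrame:
    """Long-format per-sample metric table consumed by compare_groups.

    Emits adenylation_ratio / degradation_ratio (missing when undefined),
    cpm of the three ratio species, and per-region cpm.
    """
    rows = []
    for res in results:
        for r in res.ratios:
            base = {"sample_id": res.sample_id, "precursor_id": r.precursor_id,
                    "arm_name": r.arm_name}
            total = res.profile.total_counted
            scale = 1e6 / total if total > 0 else float("nan")
            rows.extend([
                {**base, "metric": "adenylation_ratio",
                 "value": r.adenylation_ratio},
                {**base, "metric": "degradation_ratio",
                 "value": r.degradation_ratio},
                {**base, "metric": "cpm_substrate", "value": r.substrate_count * scale},
                {**base, "metric": "cpm_tailed", "value": r.tailed_count * scale},
                {**base, "metric": "cpm_trimmed", "value": r.trimmed_count * scale},
            ])
        for reg in res.regions:
            total = reg.total
            for region, count in sorted(reg.counts.items()):
                rows.append({
                    "sample_id": res.sample_id,
                    "precursor_id": reg.precursor_id,
                    "arm_name": "*",
                    "metric": f"region_cpm_{region}",
                    "value": count * 1e6 / total if total > 0 else None,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-facing stages


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, inputs: Sequence[str],
                    counters: Mapping[str, float]) -> None:
    cfg = asdict(config)
    manifest = {
        "isotail_version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": {str(p): _sha256(p) for p in inputs if p},
        "counters": dict(counters),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _load_samples(samples_tsv: str) -> pd.DataFrame:
    sheet = pd.read_csv(samples_tsv, sep="\t", dtype=str)
    if "sample_id" not in sheet.columns:
        raise ValueError("sample sheet needs a sample_id column")
    path_col = next(
        (c for c in ("fastq", "sam", "reads", "path") if c in sheet.columns), None
    )
    if path_col is None:
        raise ValueError("sample sheet needs a fastq/sam/reads/path column")
    sheet = sheet.rename(columns={path_col: "reads"})
    sheet["format"] = ["sam" if str(p).endswith(".sam") else "fastq"
                       for p in sheet["reads"]]
    return sheet


def run_simulate(config: RunConfig) -> Path:
    """Simulate an experiment into outdir/simulated (FASTQ + sheet + truth)."""
    outdir = Path(config.outdir)
    simdir = outdir / "simulated"
    sim_kwargs = dict(config.simulate)
    effects = sim_kwargs.pop("group_effects", None)
    scn = SimScenario(seed=config.seed, **sim_kwargs) if effects is None else \
        SimScenario(seed=config.seed, group_effects=effects, **sim_kwargs)
    simulate_experiment(scn, simdir)
    from .reference import write_reference

    write_reference([scn.reference], simdir / "reference.fasta",
                    simdir / "reference.tsv")
    logger.info("simulated %d group(s) into %s", len(scn.group_effects), simdir)
    return simdir


def run_quantify(config: RunConfig) -> list[SampleResult]:
    """Quantify every sample in the sheet and write the output tables."""
    config.validate_paths(["reference_fasta", "annotation", "samples_tsv"])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = load_reference(config.reference_fasta, config.annotation,
                          config.annotation_dialect)
    sheet = _load_samples(config.samples_tsv)
    base = Path(config.samples_tsv).parent
    results: list[SampleResult] = []
    inputs = [config.reference_fasta, config.annotation, config.samples_tsv]
    total_records = total_skipped = 0
    for _, row in sheet.iterrows():
        reads_path = Path(row["reads"])
        if not reads_path.is_absolute():
            reads_path = base / reads_path
        if not reads_path.exists():
            raise FileNotFoundError(f"reads file {reads_path} not found")
        inputs.append(str(reads_path))
        stats = ReadStreamStats()
        counts: dict[str, int] = {}
        hints: dict[str, tuple[str, int, int]] = {}
        if row["format"] == "sam":
            for _, seq, loc in iter_sam(reads_path, stats):
                counts[seq] = counts.get(seq, 0) + 1
                if loc is not None:
                    hints.setdefault(seq, loc)
        else:
            for _, seq in iter_fastq(reads_path, stats):
                counts[seq] = counts.get(seq, 0) + 1
        if stats.n_records and stats.n_skipped / stats.n_records > MAX_SKIP_FRACTION:
            raise RuntimeError(
                f"sample {row['sample_id']}: {stats.n_skipped}/{stats.n_records} "
                f"records malformed (> {MAX_SKIP_FRACTION:.0%}); aborting"
            )
        if stats.n_skipped:
            logger.warning("sample %s: skipped %d malformed record(s): %s",
                           row["sample_id"], stats.n_skipped, stats.skip_reasons)
        res = quantify_sequences(
            counts, refs, row["sample_id"],
            max_offset5=config.max_offset5,
            min_core_match=config.min_core_match,
            substrate_delta3=config.substrate_delta3,
            tail_nt=config.tail_nt,
            include_ambiguous=config.include_ambiguous,
            location_hints=hints or None,
        )
        res.qc["records_skipped"] = float(stats.n_skipped)
        results.append(res)
        total_records += stats.n_records
        total_skipped += stats.n_skipped
        logger.info("sample %s: %d reads in, %d assigned, %d ambiguous, %d unassigned",
                    row["sample_id"], stats.n_records, res.qc["assigned"],
                    res.qc["ambiguous"], res.qc["unassigned"])

    _write_tsv(pd.concat([profile_frame(r) for r in results], ignore_index=True)
               if results else profile_frame_empty(), outdir / "isomirs.tsv")
    _write_tsv(ratio_frame(results), outdir / "ratios.tsv")
    _write_tsv(region_frame(results), outdir / "regions.tsv")
    _write_tsv(qc_frame(results), outdir / "qc.tsv")
    _write_tsv(metric_table(results), outdir / "metrics.tsv")
    _write_manifest(outdir, config, inputs, {
        "n_samples": len(results),
        "records_total": total_records,
        "records_skipped": total_skipped,
    })
    return results


def profile_frame_empty() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "sample_id", "precursor_id", "arm_name", "offset5",
        "delta3_templated", "tail", "isoform_class", "count", "cpm",
    ])


def run_compare(config: RunConfig) -> pd.DataFrame:
    """Compare groups from a previous quantify run's metrics table."""
    if config.contrast is None:
        raise ValueError("compare requires a contrast (two group labels)")
    outdir = Path(config.outdir)
    metrics_path = outdir / "metrics.tsv"
    if not metrics_path.exists():
        raise FileNotFoundError(f"{metrics_path} not found; run quantify first")
    meta_path = config.metadata_tsv or config.samples_tsv
    if meta_path is None or not Path(meta_path).exists():
        raise FileNotFoundError("metadata TSV (sample_id, group) required")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "group" not in meta.columns:
        raise ValueError("metadata TSV needs a group column")
    metadata = dict(zip(meta["sample_id"], meta["group"]))
    table = pd.read_csv(metrics_path, sep="\t",
                        dtype={"sample_id": str, "arm_name": str})
    comparisons = compare_groups(
        table, metadata, tuple(config.contrast),
        adjust=config.adjust, welch=config.welch,
    )
    frame = comparisons_to_frame(comparisons).sort_values(
        ["precursor_id", "arm_name", "metric"]
    ).reset_index(drop=True)
    _write_tsv(frame, outdir / "comparisons.tsv")
    return frame


def run_all(config: RunConfig) -> pd.DataFrame:
    """simulate → quantify → compare in one go (simulated inputs)."""
    simdir = run_simulate(config)
    config.reference_fasta = str(simdir / "reference.fasta")
    config.annotation = str(simdir / "reference.tsv")
    config.annotation_dialect = "tsv"
    config.samples_tsv = str(simdir / "samples.tsv")
    run_quantify(config)
    if config.contrast is None:
        sim_effects = config.simulate.get("group_effects", {"control": {}})
        labels = list(sim_effects)
        if len(labels) >= 2:
            config.contrast = (labels[0], labels[1])
    if config.contrast is not None:
        return run_compare(config)
    return pd.DataFrame()
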
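# isotail

**isomiR 3′ tailing-and-trimming analysis for small RNA-seq.**

Mature miRNAs are not single sequences: sequencing libraries contain
isomiRs that differ at the 3′ end by *templated extension* (extra
nucleotides matching the precursor, e.g. the 23-nt miR-21-5p "+C"),
*non-templated tailing* (enzymatically added nucleotides, e.g. the
adenosine of "+CA" added by the non-canonical poly(A) polymerase PAPD5)
and *trimming* (3′→5′ shortening by the ribonuclease PARN). The balance
between these species is a readout of the tailing-and-trimming turnover
pathway: adenylation of a miRNA 3′ end marks it for exonucleolytic
degradation. `isotail` is a library for quantifying that balance from
adapter-free FASTQ or SAM reads, for anyone studying miRNA stability —
e.g. oncomiR regulation in HER2-amplified breast cancer, where this
pathway controls miR-21-5p levels.

## What it computes

Reads are anchored ungapped and mismatch-free to annotated mature arms
(5′ start within ±2 nt of the canonical start) and decomposed greedily,
templated-first: the read is walked along the precursor/template context
as far as it agrees; the remainder is the non-templated tail. Each read
gets a key (offset5, Δ3_templated, tail). On the three length-defined
species with canonical 5′ ends —

* substrate *S* = templated-extension isoform (23-mer "+C"),
* tailed *T* = substrate + one non-templated A (24-mer "+CA"),
* trimmed *C* = canonical-length isoform (22-mer),

two per-miRNA statistics are computed:

```
adenylation ratio = T / S        degradation ratio = C / S
```

Both are undefined (missing, never 0) when S = 0, and invariant under
count rescaling, so raw counts and cpm give identical ratios. The
package also counts reads per precursor sub-region (upstream flank,
mature 5p, loop, mature 3p, downstream flank; majority overlap, ties to
the 5′-most region) as a proxy for Drosha/Dicer processing changes, and
compares any per-sample metric between groups with the two-sample
pooled-variance Student t-test (Welch and Benjamini–Hochberg optional).

A kinetic simulator generates ground-truth libraries from a linear
three-species chain — production α, adenylation *a*, trimming *t*, basal
decay δ — whose steady state gives adenylation ratio a/(t+δ) and
degradation ratio (t/δ)·a/(t+δ), so the entire pipeline is testable
end-to-end without external data.

## Worked example

```python
from isotail import SimScenario, simulate_sample, steady_state
from isotail.pipeline import quantify_sequences

scn = SimScenario(alpha=100, a_rate=0.2, t_rate=0.3, delta=0.1, seq_error=0.0)
print(steady_state(scn).adenylation_ratio)   # 0.5 closed form

sample = simulate_sample(scn, sample_seed=11, sample_id="demo")
res = quantify_sequences(sample.sequence_counts, [scn.reference], "demo")
r = next(x for x in res.ratios if x.arm_name == "miR-sim-5p")
print(r.adenylation_ratio, r.degradation_ratio)
```

prints (run as `python examples/03_simulate_and_recover.py`):

```
closed form: adenylation=0.500 degradation=1.500
estimated from 100000 reads: adenylation=0.509 degradation=1.510
species counts: substrate=26566 tailed=13525 trimmed=40122
```

i.e. from 10⁵ simulated reads the pipeline recovers both turnover ratios
to within multinomial sampling noise. The `examples/` directory has one
short script per capability: 3′-end decomposition, ratio arithmetic,
closed-form recovery, two-group comparison, and the precursor-region
processing proxy. A thin CLI wraps the same pipeline
(`isotail simulate|quantify|compare|all`, YAML config + flag overrides),
writing per-sample isomiR/ratio/region/QC tables, a metrics table, a
comparison table and a run manifest, all deterministic for fixed inputs.

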
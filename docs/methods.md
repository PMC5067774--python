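# Methods

## Coordinate model and reference handling

All analysis is precursor-local. Annotations (FASTA + miRBase-style GFF3
or a plain TSV) are resolved at load time into 0-based, half-open,
precursor-relative intervals on the precursor's own strand;
minus-strand genomic records are reverse-complemented once, so no other
module ever sees genome coordinates. Sequences are held in the DNA
alphabet (U accepted on input, emitted on request) because read input is
DNA-alphabet FASTQ.

Judging whether a 3′ addition is templated requires sequence *beyond*
the mature end: each arm carries a template context of ≥ 10 nt starting
at the arm's 3′ end. When the arm ends well inside the precursor the
context is the remaining precursor sequence; when it ends at or near the
precursor boundary the context must be supplied explicitly (TSV column)
or, for GFF3 input, is taken from the genomic flank. Ten nucleotides is
far more than the 1–2 nt tails this pathway produces; a read whose 3′
overhang outruns the available context has the excess classified as
tail, which is the conservative direction (never inventing templated
sequence).

## Read anchoring and greedy 3′-end decomposition

A read is anchored to a mature arm if it matches the template ungapped
and mismatch-free from its 5′ end, starting within ±2 nt of the
canonical 5′ start, with at least 14 matching nt. Decomposition is
greedy templated-first: walk the read along the template until the first
disagreement; everything after is the non-templated tail. This is the
unique deterministic rule under which a templated +C extension is never
called tail while the subsequent +A is — the ambiguity when a tail
nucleotide coincides with the next template base is resolved *toward*
templated. The greedy prefix equals the maximal feasible templated
prefix over all (templated, tail) splits, which the test suite verifies
against an independent brute-force enumeration.

Zero mismatches are allowed in the templated portion: a read carrying an
internal sequencing error becomes `unassigned` rather than contaminating
an end-state class. This costs a few percent of reads (at a per-base
error of 10⁻³ over ~23 nt, ~2%) but is nearly class-symmetric for the
equal-length ratio species, so the ratios are essentially unbiased; an
error in the final base converts a read into a different (spurious) tail
species rather than into one of the three ratio species, because
substitutions preserve length.

Reads matching more than one arm are `ambiguous` and excluded from all
counting by default (optional fractional 1/n inclusion). Reads shifted
at the 5′ end are profiled (class `shifted`) but never enter ratio
species: the 22/23/24-mer series is length-defined from a fixed 5′ end,
so ratio species require offset5 = 0.

## Ratios

On the canonical-5′ species of one arm — substrate (templated extension
Δ3 = +1 by default), tailed (substrate + exactly one non-templated A)
and trimmed (the canonical-length isoform, *not* the sum of all shorter
species) — the adenylation ratio is tailed/substrate and the degradation
ratio trimmed/substrate. Longer A-tails are reported in the isomiR table
but excluded from the numerator. A zero substrate count makes both
ratios missing, not zero: propagating zeros would manufacture group
differences at low depth. Both ratios are invariant under global count
rescaling, so cpm-vs-raw-count normalisation is moot for them; cpm
(count × 10⁶ / library size, library size = assigned total by default or
a supplied denominator) is used for expression-level metrics.

## Precursor-region processing proxy

Each precursor is partitioned into upstream flank, mature 5p, loop,
mature 3p and downstream flank. Located reads (arm-anchored span, exact
substring hit, or SAM coordinates for pre-aligned input) are counted
into the region holding the majority of their bases, ties to the
5′-most region, non-overlapping reads into an `outside` bucket. The
logic: a perturbation of post-Dicer turnover moves only the affected
mature arm, while a processing (Drosha/Dicer) change moves all parts of
the primary transcript together.

## Group statistics

The comparison statistic is the classical pooled-variance two-sample
Student t-test, two-sided; Welch's variant is behind a flag, as is
Benjamini–Hochberg adjustment across miRNAs (off by default — raw
p-values are the primary output for the ratio contrasts). Groups need
≥ 2 non-missing values; zero pooled variance yields a flagged degenerate
result instead of an infinite statistic. Metrics are compared on their
natural scale; log-transformation of cpm before testing is left to the
caller.

## The kinetic simulator

The generator is a minimal linear chain, chosen as the simplest model
consistent with adenylation-marks-for-trimming turnover; it is a
modelling device of this package, not a mechanistic claim:

* substrate produced at rate α, leaves by adenylation *a* + decay δ;
* tailed species leaves by trimming *t* + decay δ;
* trimmed species leaves by decay δ.

Steady state: S_sub = α/(a+δ), S_tail = a·S_sub/(t+δ),
S_trim = t·S_tail/δ, hence adenylation ratio a/(t+δ) and degradation
ratio (t/δ)·a/(t+δ), both independent of α. Trimming is modelled as a
single jump from tailed to canonical length (removing tail plus
templated extension); intermediate lengths are not generated by default.

Libraries are drawn multinomially from the steady-state proportions,
mixed with a background of loop/opposite-arm/flank fragments, with
per-base substitution noise applied afterwards. Defaults, fixed once as
the package's study conditions: α = 100, a = 0.2, t = 0.3, δ = 0.1 (a
regime with ratios 0.5 and 1.5, i.e. strong but not saturating
turnover); depth 10⁵ reads and n = 3 samples per group, a typical
targeted small-RNA sequencing design in biological triplicate; per-base
substitution error 10⁻³, Illumina-like; background fraction 0.2 split
evenly over the non-measured regions so the processing proxy has
signal. Group effects are multiplicative factors on α, a and/or t,
applied before the steady state is solved — e.g. a 1.5× joint increase
of a and t emulates de-repressing both enzymes of the pathway, and a
fraction-series helper varies a across pseudo-fractions.

For efficiency the simulator draws species *counts* and materialises
individual reads only for the binomially-drawn error-bearing copies
(substitution count per copy from the ≥1-truncated binomial, positions
uniform without replacement); the quantifier likewise collapses input to
unique-sequence counts before matching. Neither shortcut changes the
sampled distribution. Randomness is a single root seed; per-sample seeds
derive deterministically from (root, sample index), and identical seeds
give byte-identical FASTQ and tables.

### What the simulator does not emulate

Adapter read-through, quality-score profiles, PCR duplicates, ligation
bias, multi-locus miRNA families, 5′ heterogeneity from alternative
Drosha/Dicer cuts, oligo-adenylation tail-length distributions, and a
transcriptome-wide background. Passing the simulation-based tests
therefore demonstrates correctness of the decomposition, ratio and
statistical machinery under the stated sampling model — not robustness
to every artefact of real libraries.

## Numerical and validation choices

Problem sizes in the validation harness (`isotail.evaluation`, run by
`scripts/acceptance.py` and the acceptance tests) are 10 replicate
libraries at depth 10⁵ for closed-form recovery, 100 replicate pairs for
the direction check, 100 null replicates (3+3 samples) for the type-I
error check and 10 pairs for the region-proxy contrast — sizes at which
the multinomial standard errors are small compared to the effects being
demonstrated. Standard errors for the recovery check use the
delta-method variance of a multinomial count ratio,
Var(T/S) ≈ (T/S)²(1/T + 1/S), which is the sampling model the generator
itself implements. The region-proxy flatness statistic is a paired
Poisson-scale z on summed counts. Tie-breaks: equal-length matches at
several 5′ offsets prefer the smaller |offset|, then the 5′-most;
region-overlap ties go to the 5′-most region. Degenerate inputs (empty
FASTQ, empty profiles, zero denominators, zero variance) produce empty
tables, missing values or flagged results, never silent zeros; malformed
read records are skipped and counted, with a hard error when they exceed
10% of a file.

## Known limitations

Only 3′-end chemistry is modelled (no internal editing or 5′ tailing);
the matcher is exact-match and so slightly undercounts at high error
rates; multi-mapping apportionment beyond exclusion/fractional splitting
is out of scope; and the t-test assumes approximate normality of
per-sample ratios, which holds for deep libraries but not necessarily at
very low depth, where ratios should be treated with care.
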
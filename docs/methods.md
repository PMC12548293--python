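# Methods

This note documents the models and procedures msikit implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the choices made where the design was genuinely open.

## Microsatellite catalog

The scanner reports every *maximal perfect* run of a primitive 1–3 bp motif
meeting a per-size minimum unit count (defaults: mono ≥ 5, di ≥ 3, tri ≥ 3
units; configurable). Perfect repeats only: stratifying entropy by exact
unit count requires unambiguous tract lengths, so interrupted repeats are
out of scope. Ambiguous bases terminate runs. Coordinates are 0-based
half-open internally; BED output follows BED conventions; 1-based
coordinates appear only in VCF-facing code.

Each run is phased at its leftmost base and reported once. Two phase-shifted
maximal runs of the same period can overlap by up to the motif length
(`CACACATATATA` contains both (CA)₃ and (TA)₃ sharing one base); both are
reported, since each is a genuine maximal run. Runs of different motif sizes
may overlap freely (a homopolymer inside a dinucleotide context is reported
per size).

**Canonical motifs** merge a motif with its reverse complement
(`min(motif, revcomp(motif))`), never with its rotations: GA/TC and AG/CT
are distinct groups because they describe differently phased tracts. One
consequence, documented here because it is easy to trip over: a maximal run
with a *partial* trailing unit can change rotation group when read from the
other strand (TATATAT is TA-phased forward but AT-phased in reverse
complement), so the strand-symmetry of the catalog's canonical-motif
multiset is exact only for whole-unit tracts.

## Allele spectra

A read contributes an observation at a locus only if it contains, in order,
`min_flank` (default 5) reference-matching bases on both sides of the tract;
the allele is the number of consecutive motif copies between the located
anchors *in the read sequence*. This is deliberately CIGAR-free: aligners
place indels within repeats arbitrarily, whereas anchor parsing is invariant
to that. Reads that are duplicate-marked, secondary, supplementary, unmapped
or below `min_mapq` (default 20) are ignored; Ns in the tract or anchors
fail the parse. Loci with fewer than `min_depth` (default 10) spanning
observations are flagged insufficient and excluded downstream — this
per-locus floor is distinct from the per-stratum site-count exclusion below.

## Entropy statistics and MSI scoring

Shannon entropy is computed in **bits** (log base 2; stated in every
output). SE = 0 iff the spectrum has a single distinct length;
SE ≤ log₂(k) for k lengths.

Per-sample stratification groups loci by (canonical motif, reference unit
count). For exome data, strata with fewer than 10 loci are excluded; the
exclusion is not applied to whole-genome data. The motif trend is ordinary
least squares of per-locus SE on unit count, with the 95% CI on the slope
from the t distribution on residual degrees of freedom; at least three
distinct unit counts are required.

Tumor-only scoring needs a per-locus instability call. msikit uses
total-variation distance to a pooled normal baseline:

- baseline proportions: per locus, read counts pooled over all normals
  (loci missing from any contributing normal are dropped and logged);
- threshold: τ = mean + 3·SD of each normal's leave-one-out distance to the
  pool of the others; identical normals collapse τ to zero, where the floor
  applies; a single-normal baseline uses τ = 0.1;
- call: unstable iff d > max(τ, τ_floor) with τ_floor = 0.05, ties stable;
- MSI score = unstable / evaluated loci, with per-locus distances emitted
  for audit.

These rules are declared, configurable and recorded in every baseline file.
Absolute scores are therefore not comparable to scores from other tools with
other instability criteria; contrasts between samples scored against the
same baseline are the meaningful quantity.

## Reporter-gene calculus

Overall MF = mutant colonies / screened colonies per mouse. Per-class MF =
overall MF × (class count / classified mutations), so the class MFs
partition the overall MF exactly. Group values are per-mouse means (a pooled
mode — group mean MF apportioned by pooled class counts — is provided as an
option). Two-group comparisons use the Mann–Whitney U test.

Class scheme: the six Watson–Crick substitution pair classes (C>T and G>A
both count as G:C>A:T, etc.); 1-bp indels of A or T inside an A/T
homopolymer run of length ≥ 2 are `1-indel_(A)n` with that run length
(run 1 is a plain `1-indel`, and run length ≥ 2 qualifies because published
run-length tables tabulate (A)₂); AA/TT 2-bp indels in such runs are
`2-indel_(A)n`; other 1-bp indels are `1-indel`; indels over 2 bp are
`>2bp_indel`; anything else is `other`. A and T runs are both "(A)n" context
because the assay reads one strand of a double-stranded tract. Indel
positions are normalized to the run's leftmost base (placement within a
homopolymer is ambiguous). Multi-mutation colonies contribute each mutation
once; no colony-level deduplication is applied.

The packaged published MF tables (per-class, and adenine 1-indel by run
length) are transcriptions used by the worked-value checks; the published
fold ratios the package reports are computed from them, not asserted.

## Somatic filtering and matrix classification

Filtering retains a variant only if it passes all of: tumor depth ≥ 10,
normal depth ≥ 10, tumor alt reads ≥ 3, normal alt reads = 0, chromosome not
X/Y/M, not in dbSNP, not shared by ≥ 2 tumors. dbSNP membership and
shared-tumor counts are consumed as precomputed input flags. The rejection
tally is keyed by the first failed rule in that fixed order, but retention
itself is order-free (the rules commute). Chromosome-name dialects
("chrX" vs "X") are normalized on ingest.

SBS96: purine-reference substitutions are reverse-complemented together with
their immediate 5′/3′ context onto the pyrimidine strand; each of the 96
channels receives exactly two of the 192 strand-specific combinations.

ID83: indels are left-aligned first. 1-bp events are keyed by base (A/T→T,
C/G→C) and homopolymer run length — counting the deleted base for deletions
(internal category 5 = run of 6+ before deletion) and the adjacent reference
run for insertions. Longer deletions are repeat-type when a tandem copy of
the deleted sequence flanks them, with the category counting the *remaining*
copies (capped 5+; a deletion of one unit from a 7-copy tract is category
5+, i.e. more than six copies including the deleted one); deletions with no
tandem copy but positive boundary microhomology use the microhomology
length; insertions count existing reference copies. After left-alignment
microhomology can only occur on the right flank, which is where it is
measured. Channel ids follow the standard `size:kind:context:category`
layout and the fixed 83-channel order, so the matrices drop into downstream
signature tooling unchanged.

## Integration-site detection

Pairs with exactly one host-mapped mate (MAPQ ≥ 20) and one unmapped mate
are the primary signal; the unmapped mate is re-aligned to the plasmid with
the built-in seed-and-extend aligner — exact 15-mer seeds, best diagonal by
seed vote, banded (±12) local Smith-Waterman-style extension with match +1,
mismatch −2, gap −3 (declared constants, not tuned) — and kept when the
score reaches 80% of the maximum attainable (query length × match). Host
positions of the evidence are clustered by single linkage with gap ≤ 1000 bp
and clusters with ≥ 3 pairs become calls. A tandem multi-copy insertion
yields many pairs with *both* mates unmapped (plasmid-internal fragments);
these carry no host position and are only informative through the reciprocal
pass (enabled when a host reference is supplied): if exactly one mate of a
both-unmapped pair hits the plasmid, the partner is re-checked against the
host and merged into the evidence. Split-read (soft-clip) mining is off by
default. The reported call interval spans the evidence positions, so the
true junction lies within roughly one fragment length of the interval.

## Synthetic data: what it emulates, and what it does not

The slippage model gives each read at a locus of unit count n probability

p(n) = min(0.5, p0 · m · (n − n_min + 1)^γ)

of carrying a slipped allele, with p0 = 0.002, γ = 1.5, genotype multiplier
m = 1 (stable) or 5 (MMR-deficient), and n_min the catalog's minimum unit
count for that motif size. The ceiling is applied after the multiplier: an
unbounded product would saturate at certainty for long repeats, flattening
the deficient condition's entropy-length slope and inverting the very
ordering the model exists to express; capping at 0.5 keeps the slipped
fraction a minority at every length and the slope ordering strict. Steps are
−1 unit with probability 0.7, +1 with 0.2 (contraction-biased, matching
deletion-dominated spectra), and the remaining 0.1 mass is geometric over
magnitudes ≥ 2 with the sign split in the same 0.7:0.2 ratio. PCR-stutter
jitter is a separate default-off parameter so instability and noise are
independently testable.

Reference simulation plants perfect repeats in background sequence generated
under constraints (no mono run ≥ 3, no period-2 run ≥ 5 bases, no period-3
run ≥ 7 bases) with breaker bases at tract boundaries, so the scanner
recovers exactly the planted truth — which is what makes the round-trip
tests exact rather than statistical. Read emission places every observation
with intact 20 bp flanks; with noise off, extraction reproduces the emitted
spectra bit-for-bit.

The reporter generator draws mutant counts Binomial(n_km, rate), classes
from a rate table whose defaults put ~77% of mass on (A)n 1-indels
(matching the structure of MMR-deficient spectra), and (A)n positions across
runs with weight run_length⁴. The synthetic reporter reference is a
constructed 134 bp stand-in (the real reporter CDS is not distributed here)
with adenine runs of lengths 2–6 and (A)₆ the longest, mirroring the
assay's context structure.

The integration generator samples fragments (length Normal(350, 30), reads
100 bp) across the modified genome and emits a host-referenced SAM in which
any read touching plasmid or junction sequence is unmapped.

All generators derive per-locus/sample/fragment RNG streams from the global
seed plus a stable key hash, so identical seeds give byte-identical output
and adding a locus or sample never perturbs other draws.

**Not emulated:** sequencing error profiles, base qualities, mapping
artifacts, tumor purity, coverage biases, genome-scale repeat landscapes.
Passing tests therefore demonstrate the correctness and statistical behavior
of the *computations* under the declared generative model — not performance
on real libraries, where alignment noise and stutter would add variance the
baseline calibration has to absorb.

## Problem sizes used by the quantitative checks

Chosen as desk-scale study conditions: entropy-slope contrast — 200 loci per
motif (mono-A and CA, unit counts 5–14), depth 50, 100 replicates; MSI
contrast — 121 mono-A loci (unit counts 5–15), 20-normal baselines, depth
50, 100 replicates; run-length trend — 4 mice × 500 000 colonies at rate
5 × 10⁻⁴, 100 replicates; integration recovery — 25 kb host, 3 kb plasmid ×
4 tandem copies, 25× depth, 20 replicates each with and without transgene.

## Known limitations

- Absolute MSI scores depend on the declared instability criterion and are
  not comparable across tools or cohorts scored against different baselines.
- The scanner is written for desk-scale references (≤ ~10 Mb); it is exact
  but not engineered for whole-genome throughput.
- The per-locus instability threshold assumes normals share the sample's
  depth regime; strongly unequal depths widen leave-one-out distances and
  inflate τ.
- Reporter per-class MFs are undefined for a mouse with mutants but no
  classified mutations (flagged as missing rather than imputed).
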
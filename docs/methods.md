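# Methods

This note documents the models and procedures implemented in `multiguide`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and known limitations.

## Guide selection

A usable target is a 23-nt window whose protospacer starts `GG` (so T7
transcription can initiate on the guide's own 5' end without appending
extra bases) and whose last three bases form the SpCas9 PAM `NGG`. The rule
is applied literally: position 21 of the 23-mer (the PAM's N) is free,
positions 1–2 and 22–23 are fixed `GG`.

* Coordinates are 0-based half-open on the forward strand; minus-strand
  hits report their sequence in target orientation. This makes interval
  arithmetic (e.g. SNP masking) unambiguous.
* Windows containing `N` are skipped: the PAM rule is undefined on `N`.
* Overlapping and nested hits are all reported; deduplication is a
  presentation concern, not a scanning one.
* Ranking uses |start − CDS start| in nt. Ties break plus strand first,
  then lower coordinate — a stable, seed-free order.
* SNP exclusion takes a plain list of forward-strand positions rather than
  a VCF; any target whose interval contains a masked position is dropped.

## Template assembly

The transcription template is `T7(21 nt) + target(23 nt) + scaffold(81 nt)`
= 125 nt. The scaffold is the extended sgRNA constant (with 3'
tracrRNA-derived extension); the template retains the PAM between spacer
and scaffold, matching the reference design this toolkit reproduces. That
inclusion is unusual for sgRNA design, so `build_template` exposes
`include_pam_in_spacer=False` (122 nt) as an explicit alternative.

`split_template` cuts the duplex template at two junctions into three
fragments / six oligos under these constraints:

* every oligo 38–46 nt (synthesis-accuracy sweet spot for chemical
  oligos);
* outer template ends blunt (they must not ligate);
* all target-dependent bases — the 20-nt protospacer plus the PAM's N —
  confined to fragment 1, so re-targeting changes exactly two oligos. The
  PAM's `GG` is invariant and may sit on fragment 2's constant oligo;
* junction overhangs (default 4 nt; 3 and 5 supported) pairwise
  non-complementary, non-palindromic, and distinct, so that the only
  possible ligation is F1–F2–F3 in order and no end can close a circle.

The solver scans junction placements deterministically, preferring the most
balanced oligo lengths, and returns the first admissible design — the same
template always yields the same oligos. For the 125-nt template with 4-nt
overhangs this lands on top-strand cuts 42/82 and bottom-strand cuts 46/86,
with overhangs `GGGT` (PAM-GG + scaffold GT) and `TCCG` (scaffold), both in
constant sequence. A 5-nt overhang cannot simultaneously confine the
variable bases to fragment 1 and respect the 46-nt cap for this geometry;
the solver reports the violated constraint rather than emitting a bad
design.

`simulate_ligation` is the verifier: fragments join wherever sticky ends
have the same protrusion chemistry (5'/5' or 3'/3') and Watson–Crick
complementary single strands; blunt ends never ligate; each fragment is
used at most once per product and both orientations are explored. All
maximal products (chains no remaining fragment can extend) are returned,
labelled linear or circular, deduplicated up to reading direction and
rotation. Every emitted design must produce exactly one product — the
full-length linear template — and zero circular products.

## Indel calling

Mutant alleles (one resolved sequence per fish–gene, as obtained from
Sanger genotyping of outcrossed F1 animals) are globally aligned to the
wild-type amplicon with affine gap penalties: match +1, mismatch −2, gap
open −5, gap extend −1 (`multiguide.indels.ALIGN_SCORES`). These constants
make the published founder-table alignments optimal for their pairs.
Biopython's `PairwiseAligner` performs the alignment; gap runs are then
left-shifted to a canonical placement (placement inside a repeat is
degenerate and never affects the call).

Gap runs in the allele row are deletions, runs in the wild-type row
insertions. One allele yields one event whose components are all its gap
runs. Classes: `deletion`, `insertion`, `complex` (at least one of each),
`none`. Frameshift: net change not divisible by 3 (never for `none`).
Labels render the net change first and parenthesise the component totals
only for complex alleles: `-8`, `+1`, `+2 (-5, +7)`. Aligned mismatches are
reported in a substitution side channel and never contribute to the class —
genotype tables record indels only.

**Identifiability limit.** A complex event whose smaller component is small
(≲6 nt) cannot be recovered as "complex" from the sequence pair: under any
parsimony scoring in which opening a second gap costs more than a
mismatch, the optimal alignment explains such an allele as a single net gap
plus substitutions (e.g. a planted −6/+1 aligns as −5 with one
substitution). The net length change — and hence the frameshift verdict —
always survives; only the component decomposition collapses. Published
component breakdowns of small complex alleles come from visual inspection
of traces and are therefore accepted as label inputs rather than re-derived
from sequence.

## Cohort summaries

Founder screens mix two denominators and this package reports both
explicitly:

* **events** — every mutated cell of the fish × gene matrix; the
  deletion/insertion/complex percentages use this (two fish carrying the
  same allele count twice);
* **distinct types** — unique (gene, label) pairs; the frameshift fraction
  uses this.

Per-gene efficiency is 100 × (fish with a mutation in the gene) / (fish
screened), reported at 2 decimals; the cohort mean is the unweighted mean
over genes, additionally reported at integer precision. The positive rate
is the percentage of fish with at least one mutation anywhere.

## Phenotype statistics

A C-start trial is a response iff a latency was recorded and it is ≤ the
gate (default 25 ms, inclusive — "within 25 ms"). The no-response marker in
trial TSVs is an empty field, never 0, because 0 ms is a legal latency.
Rates are per fish (responses / trials delivered); fish with zero trials
are excluded with a warning.

Group comparisons run on per-fish rates — the fish, not the trial, is the
independent unit. Welch's unequal-variance t is the default (robust to the
variance heterogeneity that different response rates imply); Student's t, a
two-sided label-permutation test (+1 smoothing, so p ≥ 1/(n_perm+1)), and a
pooled-trial chi-square (sensitivity analysis for the pooling question) are
available. Staining intensity is summarised as 100 × mean(mutant) /
mean(control) with a Welch t on the raw values; count summaries report
group means at 2 decimals and flag single-animal groups instead of testing
them.

## Synthetic data

The generators define the reference conditions the tests run under; all
randomness flows through one explicitly passed numpy `Generator`.

* **Exons** (`synth_exon`): i.i.d. uniform background with `GG N18 NGG`
  motifs planted at non-overlapping positions on random strands. In
  collision-free mode the sequence is resampled until a both-strand scan
  finds exactly the planted hits, giving scanner tests an exact ground
  truth. Not emulated: codon structure, GC bias, introns.
* **Alleles** (`synth_alleles`): requested deletions/insertions placed in
  the 23-nt target window; inserted bases never extend adjacent repeat
  context, and complex events keep ≥ 6 matched bases between components.
  In collision-free mode, randomised complex placements are resampled
  until the planted event is what the aligner recovers (see the
  identifiability limit above); specs with pinned coordinates are emitted
  verbatim. Not emulated: microhomology-biased repair spectra, mosaicism
  within a fish.
* **C-start trials**: independent Bernoulli(p) trials per fish, 10 per
  fish and 48 fish per group by default — the published screen design —
  with rates 0.6854 (wild type), 0.4354 (*tmem183a*), 0.6688
  (*zgc103499*). Response latencies are Uniform(4, 24) ms so every scored
  response falls inside the gate; non-responses are empty. Optional
  per-fish Beta-distributed rates model fish-to-fish heterogeneity, which
  the default (exchangeable Bernoulli) deliberately omits — that is
  exactly the assumption a per-fish-rate t-test makes, and the option
  exists to probe it. Habituation across trials is not modelled.
* **Intensities**: Gaussian with CV 10% by default (typical replicate
  spread for cluster-averaged fluorescence), clipped at 0; reference means
  64.66 (mutant) vs 100 (control) at n = 35/32.
* **Counts**: rounded Gaussian with sd 2.0 clipped at 0 (hair-cell cluster
  counts near 10 are over-dispersed relative to Poisson sampling of rare
  events but far tighter than Poisson at this mean); reference means 10.4
  vs 7.34 at n = 33/38.

Because the generators are idealised, passing recovery tests demonstrate
that the *analysis* is unbiased and appropriately powered at the published
design sizes — not that real screens meet the generators' assumptions
(independence across trials, Gaussian intensities, no mosaicism).

Under the binomial trial model the group mean rate at the 48 × 10 design
has a standard error of √(p(1−p)/10)/√48 ≈ 2.1 percentage points at
p = 0.6854, so single-screen rate estimates scatter roughly ±4.2 points at
95%; the reproduction script therefore averages 25 replicate screens when
reporting recovered rates.

## Numerical and interface choices

* Sequences are uppercase `ACGTN`; `U` is converted to `T` on FASTA input
  with a warning. FASTA is written wrapped at 60 columns.
* Labels use ASCII `+`/`-`; the parser also accepts the typographic minus
  found in printed tables.
* Percentages are rounded to 2 decimals at the reporting boundary;
  internal arithmetic is unrounded.
* Problem sizes in tests and the reproduction script follow the published
  design (6 fish × 5 genes; 48 fish × 10 trials; n = 35/32 and 38/33), with
  200 replicates for power/recovery checks and 1000 for type-I
  calibration.

## Known limitations

* No on-/off-target activity scoring; candidate ranking is by CDS
  proximity only.
* No chromatogram (.ab1) parsing or mosaic F0 trace deconvolution — input
  is one resolved allele per fish–gene.
* The ligation model is combinatorial (perfect-match sticky ends, no
  mismatch tolerance, no blunt ligation, no melting-temperature or
  secondary-structure modelling).
* The complex-allele class is unidentifiable from sequence when a
  component is small (see above).
* Germline-transmission and breeding-scheme modelling are out of scope.
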
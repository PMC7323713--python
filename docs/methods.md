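# Methods

This note documents the models and procedures implemented in `somakit`,
the choices made where the design was genuinely open, and what the
synthetic cohort does and does not establish about real data.

## Scope and inputs

The package consumes per-sample somatic *calls* — SNV tables (TSV or VCF
with trinucleotide context), SV breakend pairs (BEDPE), and copy-number
segments (SEG) — plus a gene BED, a 96-channel reference signature catalog,
a clinical covariate table, and a local gene–drug table.  Read alignment,
raw variant calling, segmentation (CBS) and functional annotation are
upstream of the package and out of scope.  Internally all coordinates are
1-based inclusive; BED/BEDPE/SEG conversions happen only in `io_formats`.
The `in_repeat` flag on SV records is an input annotation, not computed
from a repeat track.

## SV classification, filtering, merging

Breakend strand encodes read-pair orientation: `+` means the joined
segment ends at the breakend coming from lower coordinates.  Under this
single documented convention the intrachromosomal classes are forced:
`(+,−)` deletion, `(−,+)` tandem duplication, `(+,+)`/`(−,−)` inversion;
different chromosomes give a translocation.

Filtering applies record-level thresholds modeled on a two-stage
tumor/normal pipeline: support reads ≥ 2, control variant reads ≤ 1,
VAF ≥ 0.07, control depth ≥ 10, overhang ≥ 100 bp, inversion span ≥ 1 kb,
and removal of simple-repeat calls.  Because the package consumes call
records rather than raw reads, the stricter filter-stage values govern;
the looser call-stage values (control ≤ 10, overhang ≥ 50) are retained in
`SvFilterParams` for provenance only.  All thresholds are inclusive
(boundary values pass), "control depth ≥ 10" is read as a quality floor on
normal-sample coverage, and each rejected record is tallied under its
first failing rule in a documented rule order.

Two-caller merging matches records of the same sample and class whose
breakends both lie within `tol_bp` (default 100 bp).  Matching is greedy,
nearest pair first (L1 breakend distance), deterministically ordered, and
run to maximality, so no unmatched cross-callset pair remains.  The merged
record keeps the union of caller ids and the evidence fields of the
higher-support member.  Greedy matching can in principle differ from the
maximum-cardinality matching on adversarial chains; on jittered-duplicate
call sets (the realistic case) the tests verify it attains the optimum
computed by an independent bipartite-matching oracle.

Gene-level recurrence counts a gene as affected in a sample if either
breakend of a kept SV lies inside the gene (inclusive) or a deletion spans
it entirely; both rules are active by default and separable by flags.

## Fold-back inversions, BFB

A fold-back candidate is an inversion whose breakends are `< 20 kb` apart
(strict).  It is discarded when a reciprocal partner exists — an inversion
of the opposite strand pair with both breakends within 1 kb (the partner
window is a package choice; no distance is standard) — or when no
copy-number step ≥ `min_cn_step` (default 1 copy) exists between the
segment at either breakend and its neighbour.  A (sample, chromosome)
carrying any fold-back receives a BFB call.  Telomere loss (terminal
segment within 100 kb of a chromosome end below the sample's length-modal
copy number) is reported as corroborating evidence but does not gate the
call, since the defining criteria are the three above.  Amplified genes
are those overlapping fold-back-adjacent segments with copy number ≥ 5.

## Kataegis

A qualifying run is ≥ 6 consecutive mutations (per sample and chromosome,
position-sorted) whose n−1 inter-mutation distances average ≤ 1 kb.
"Consecutive" means adjacent in sorted order regardless of substitution
class, and no absolute span cap is imposed beyond the mean rule.  Maximal
qualifying runs are found exactly (for every start index, the farthest
qualifying end); overlapping runs merge left-to-right only when the merged
run itself still satisfies the mean rule — unconditional merging can
construct a locus that violates its own definition, which the package
forbids on outputs.  Reported loci carry the distance to the nearest SV
breakend when SVs are supplied.  Rainfall tables (inter-mutation distance
vs. position, never crossing chromosomes) support visual inspection.

## Chromothripsis

Per sample and chromosome, every window of 50 kb holding strictly more
than 10 SV breakends is a candidate; overlapping candidate windows merge
into one cluster extent.  Copy-number "regular oscillation" is quantified
as the fraction of adjacent segment pairs (segments overlapping the
extent, sorted) that alternate between the two modal rounded copy-number
states; a call passes at fraction ≥ 0.8.  A strictly monotone staircase of
states scores well below any reasonable threshold (≤ 1/(n−1)); a
two-state alternation scores 1.  The 0.8 default operationalizes an
otherwise unquantified "regular" and is exposed as a flag.

## Mutational signatures

Catalogs use the fixed 96-channel order (classes C>A, C>G, C>T, T>A, T>C,
T>G; within a class 5′ then 3′ base, each A,C,G,T; labels `A[C>A]A` …
`T[T>G]T`), with purine-reference substitutions reverse-complemented onto
the pyrimidine strand.

Extraction minimizes generalized KL divergence by multiplicative updates
with automatic-relevance-determination shrinkage: each component carries
an L1 (exponential-prior) penalty whose scale is re-estimated in closed
form every sweep, so redundant components decay.  The run starts at
`k_max`, keeps the best of `n_restarts` (default 5) initializations by
penalized objective, prunes components holding < 1% of total exposure,
then polishes the survivors with plain KL-NMF.  W columns are renormalized
to sum to 1 with the mass moved into H, leaving the reconstruction
unchanged; at convergence column sums of W·H match the catalog's column
sums, so exposures conserve per-sample mutation counts to within 1%.
Both update loops are provably non-increasing in their objectives and the
tests assert this per iteration.  Defaults (10,000 max iterations,
relative tolerance 1e−10, 5 restarts) were set so restart selection
reliably escapes over-split local optima; all runs are deterministic given
the seed.  This is a maximum-a-posteriori, deterministic stand-in for a
fully Bayesian NMF: it reproduces the automatic rank selection mechanism
with testable code.

Matching reports, for each extracted signature, the argmax-cosine
reference column and the full score list; `matched` requires cosine ≥ 0.7.
Exposure–covariate association uses the Wilcoxon rank-sum test — exact by
dynamic-programming enumeration over all C(n, m) midrank arrangements when
both groups have ≤ 10 samples (ties handled exactly; two-sided
p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))), the normal approximation with tie
and continuity corrections otherwise — or Welch's t-test behind a flag
(the two appear interchangeably in the literature this targets; neither is
asserted as canonical).  Raw p-values are reported with Benjamini–Hochberg
q-values across signatures, plus a total-burden comparison.

## Recurrent CNAs and druggable genes

Segment log2 ratios are averaged into fixed 1 Mb bins (length-weighted;
uncovered bins are NaN, treated as 0 in the null).  Per bin and direction
(amp: log2 ≥ 0.3; del: ≤ −0.3; inclusive), the G-score is the altered
fraction times the mean |log2| among altered samples.  The null cyclically
rotates each sample's whole bin vector by an independent uniform offset —
preserving each sample's value multiset and autocorrelation — with
empirical p = fraction of null scores ≥ observed (an exhaustive mode
enumerates every offset combination on tiny instances).  Benjamini–
Hochberg q-values are computed within direction; bins with q ≤ 0.25 merge
into regions only when adjacent, same-chromosome and same-direction.  The
region's frequency and G-score are those of its peak bin.  This
frequency × amplitude score with a permutation null is a stated
simplification of peak-calling recurrence tools: region boundaries are
bin-resolution and no peel-off or arm-level separation is attempted.

Druggability: a gene is druggable when the local gene–drug table records
at least one interaction (symbols matched upper-case); the three-set
membership summary reports all seven Venn cells over the union of the
SNV-, SV- and CNA-altered gene sets, so the cells always partition that
union.

## The synthetic cohort

`synthetic.SimulationConfig` defaults define the study conditions: 20
samples on an 8-chromosome, 50 Mb-each genome; ~5,000 SNVs per sample
(matching a cohort of ~10⁵ SNVs over 20 tumors); four truth signatures
(sparse Dirichlet draws, concentration 0.03, pairwise cosine < 0.1);
kataegis clusters (2 per affected sample, 8 mutations, gaps ≤ 400 bp) in 6
samples; ~30 background SVs per sample in the four classes at the
published class proportions; fold-back inversions in 14 samples — 8
flanking the recurrent amplicon (copy 6 vs 2), 6 at a second amplified
locus — with spans 5–15 kb and no reciprocal partners; one chromothripsis
sample with 12 breakpoints in ~31 kb over segments alternating between
copy 2 and 3 (its inversions planted as a reciprocal pair so they never
masquerade as fold-backs); a recurrent amplification in 14 samples and
deletion in 16; and a binary smoking-like covariate in 14 samples.  The
union of complex-event carriers is 15 of 20 by construction.  Background
SV sizes (50 kb–2 Mb) sit above the fold-back span bound, and background
SNVs are uniform per chromosome, so false planted-event mimics are
vanishingly rare and the detectors' false-positive behaviour is
analytically known.

The exposure-mixing law deserves its own paragraph because it was the one
genuinely contested design point.  The covariate-linked signature carries
a Beta(2.5, 10) baseline weight — present in every sample at a moderate,
variable level, like the flat smoking/age-related processes; the
remaining mass is split among the sporadic signatures by a Dirichlet(0.5);
the first three samples are anchor tumors each dominated by one sporadic
signature (90% of the sporadic mass), emulating the signature-dominated
hypermutators real cohorts contain; and the covariate multiplies the
linked signature's mutation count by 3 in positive samples.  A symmetric
Dirichlet alone cannot serve here: dense mixing (large α) makes the NMF
rotationally ambiguous even for an oracle fit, while sparse mixing (small
α) leaves the rank-sum comparison underpowered at n = 20.  The adopted
law is identifiable (anchors give separability) and powered, and each of
its features corresponds to a structure observed in real cohorts.  One
known artifact: because the multiplier acts on counts, covariate-positive
samples carry ~1.3× higher total burden, whereas the motivating cohort
reports no burden difference between groups.

Copy-number truth is emitted directly as segments (baseline copy 2,
log2 ~ N(0, 0.03²)); no read-depth simulation is attempted.  Trinucleotide
contexts are drawn from the channel definition itself (uniform context
frequencies), so catalog arithmetic needs no reference genome.  Caller
noise (`inject_caller_noise`) derives two call sets by independent drops,
duplicates and bounded position jitter.

What passing tests show — and do not show.  On this generator the
detectors recover every planted event and reject the planted negatives;
that validates the implementations against their printed definitions, not
the definitions' sensitivity or specificity on real tumors, where
breakpoint clustering, repeat structure, purity and subclonality violate
the generator's independence assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run the full cohort at its default size
(~10⁵ SNVs, ~700 SVs) in seconds, signature recovery over 10 catalogs, the
covariate association over 100 simulated cohorts (ground-truth exposures
through the test machinery), and null calibration over 50 flat cohorts of
10 samples × 30 bins at 200 permutations — sizes chosen so the whole suite
completes in a few minutes on one core.  Degenerate inputs are defined
throughout: empty SV sets merge to the other set; samples without CN
segments fail the fold-back CN criterion with a warning; uncovered regions
are neutral; degenerate covariate groups yield absent p-values; all-zero
catalogs are hard errors.  Ties break deterministically (merge candidates
by distance then sort key; modal CN states by count then value; reference
matches by score then name).
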
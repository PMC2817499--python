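# Methods

## Digestion model

A genome is a set of chromosome sequences per haplotype plus a methylation
overlay mapping individual recognition-site starts to one of five states:
`unmethylated`, `internal_C` (C^mCGG), `outer_C` (^mCCGG), `both_C`
(^mC^mCGG), and `cpg_methylated` (for non-CCGG sites such as NotI's).
Cleavability is a pure function of (enzyme sensitivity table, site state):
MspI is blocked by `outer_C`/`both_C`; HpaII additionally by `internal_C`
(and by `cpg_methylated`, which for a CCGG site denotes the same internal
CpG); BamHI is insensitive; NotI is blocked by `cpg_methylated`. NotI
sensitivity is configurable but inert under overlays that never annotate
NotI sites — the packaged fixture never does, since the modelled experiment
did not exercise it.

Coordinates are 0-based half-open; a cut position is the top-strand cut
(`site start + cut_offset`), and fragment lengths are differences of cut
positions. The few-nt overhang asymmetry is ignored: RLGS resolution is
orders of magnitude coarser. All four built-in enzymes have palindromic
sites and are scanned on the forward strand only; user-defined
non-palindromic enzymes are scanned on both strands. Overlapping recognition
windows are all reported and cleave independently; the fragment walk simply
takes the nearest cleavable cut in walking order.

Fragment enumeration walks from every cleavable NotI cut in both
directions: the 1D end is the nearest cleavable second-enzyme or NotI cut
(NotI–NotI fragments are kept; in reality they are double-labelled, but each
landmark-direction still contributes one intensity quantum — a stated
simplification), else the chromosome boundary (`sequence_end`). The 2D end
is the nearest cleavable BamHI cut strictly inside the 1D extent, else the
fragment runs undigested on the gel diagonal. An independent brute-force
oracle in the test suite performs the three digests literally and agrees
with the walker on hundreds of random sequences with random overlays.

## Gel model

Mobility per dimension is `x(L) = (log10 Lmax − log10 L)/(log10 Lmax −
log10 Lmin)`, strictly decreasing, 0/1 at the window edges. Only relative
positions matter to the comparisons, so no polymer physics is modelled.
Detection windows default to 500–25,000 bp (1D) and 100–5,000 bp (2D); the
physical gel dimensions of the original apparatus cannot be converted to bp
ranges without calibration data, so the windows are configuration that
brackets typical RLGS agarose/polyacrylamide resolution. `sequence_end`
fragments are excluded by default (physical ends are ddNTP-blocked before
labelling; shear ends are unknowable in silico); diagonal fragments are
retained by default.

## Spots, merging, comparison

Each in-window fragment contributes an intensity quantum of 0.5 (one allele
of one locus). Co-migrating contributions — relative length difference
≤ 1% in both dimensions, configurable — are merged by single linkage with a
deterministic representative (first member in (chrom, landmark cut,
direction, haplotype) order) and summed intensities. Spot matching across
patterns uses the same length-relative tolerance with greedy
nearest-neighbour assignment, ties broken by gel distance then smaller 1D
length, so results do not depend on gel parameters or input order.

Intensity classification is relative to a baseline that defaults to the
pattern's own modal spot intensity (the "surrounding spots"); bands are
`full` within 10% of the baseline, `half` within 10% of half of it, `absent`
at zero, `other` elsewhere. The 10% tolerance is a design choice: the
original visual halving judgement carries no stated threshold. Ties in the
mode break toward the larger intensity so half-spots never become their own
baseline. [MspI]-vs-[HpaII] calls: a spot only in [MspI] is a homozygous
internal-C call; present in both at half the [MspI] intensity, a
heterozygous one. A spot absent from both patterns is not callable from
patterns alone — sequence polymorphism and blocking methylation are
indistinguishable without site-level confirmation, which is out of scope —
and is reported only as `blocked_or_absent` when a genome explains it.

## Segregation testing

Progeny classes map to allele dosage (full/half/absent = 2/1/0
spot-producing alleles). Expectations come from Mendelian gamete
probabilities (1/2 per allele); tests are exact: the two-sided binomial
(two-sidedness by summing all outcomes no more probable than the observed,
scipy's convention) for two classes, and an exact multinomial for three or
more, fully enumerated for n ≤ 20 and Monte-Carlo estimated (fixed seed,
100,000 draws, add-one correction) beyond. The multinomial reduces exactly
to the binomial when classes collapse to two. For the canonical nine-of-nine
half-intensity selfed panel against 1:2:1, the observed outcome's
probability is (1/2)^9 ≈ 0.00195 and the full min-likelihood p-value is
0.01009 — comfortably flagged at α = 0.05. Loci within one run are
BH-corrected (the modelled study reported no multiplicity handling; a
default must exist); individuals classified `other` are excluded from the
test and surfaced in a QC column.

## Synthetic data

`build_genome` plants exact site layouts (offsets are distances between cut
positions, hence equal to the fragment lengths they produce) in uniform
random A/C/G/T background. Within a 100 bp guard around each planted locus,
accidental NotI/CCGG/BamHI occurrences are resampled away so the focal
geometry is exact; elsewhere accidental sites are kept and form the shared
background pattern. Random draws never depend on allele variants, so
haplotypes built from one seed share their background byte-for-byte; the
B-absent allele differs only by a single-base ablation of the BamHI
hexamer, chosen from a fixed candidate list and verified not to create a new
site.

The packaged fixture uses one 120 kb chromosome with the focal locus at
NotI cut 10,000: BamHI cut +1,400, MspI/HpaII cut +2,400, next NotI cut
+3,000, reproducing the spot-200 geometry (focal spot at (2400, 1400); the
blocking-methylated allele instead yields (3000, 1400)). Six filler landmark
loci with distinct geometries are planted identically in every haplotype;
they provide the deterministic full-intensity "surrounding spots" against
which halving is judged, making the modal baseline robust to the background
seed. Panel sizes default to the modelled study design: nine reciprocal F1
individuals each, nine selfed progeny of the heterozygous parent, four of
the other.

Transmission models: `mendelian` (each parent transmits one of its two
(allele, epiallele) pairs with probability 1/2); `maintain_heterozygous`
(Mendelian allele transmission, but progeny carrying the focal parent's
spot-capable allele have the M-site methylation re-established to reproduce
the parent's half-intensity configuration, with a maintenance probability
defaulting to 1); `demethylate_progeny` (transmitted focal epialleles
erased). The maintenance model is a phenomenological stand-in for the
observed selfed-progeny behaviour — pattern data cannot distinguish
maintenance from re-establishment, and the model names make no mechanistic
claim.

What the generator does *not* emulate: real chromosome-scale sequence
composition (CpG islands, repeats), recombination, partial digestion, spot
shape/exposure effects, or measurement noise on intensities. Passing tests
therefore demonstrate the correctness of the digestion/segregation logic
under clean conditions, not robustness to image-analysis noise in scanned
autoradiographs.

## Problem sizes and numerics

Simulated checks use 2,000 F1 individuals for the 1:1 segregation ratio
(accepted within 3 binomial standard errors), 500 replicate selfed panels of
n = 9 for type-I control of the non-Mendelian flag (observed rate ≈ 0.044 at
α = 0.05, bound 0.07), and 200 random 5 kb genomes for the brute-force
digestion cross-check — sizes at which every run completes in seconds while
keeping Monte-Carlo error well inside the asserted bounds. Exact-test
enumeration caps at n = 20 (231 outcomes for three classes); outcome-
probability comparisons use scipy's 1+1e-7 relative slack so the two- and
k-class paths agree bit-for-bit. Degenerate inputs are defined, not special-
cased: empty genomes give empty patterns, zero-size panels are valid for
simulation but rejected by the tests, and observations in zero-probability
classes give p = 0.

## Known limitations

Spot identity is positional: loci engineered (or occurring) with identical
fragment lengths co-migrate into one spot, exactly as on a physical gel, so
per-locus analyses require distinguishable geometries. Intensity is a noise-
free allele count in units of 0.5, which makes the half/full classification
sharper than densitometry of real autoradiographs. The segregation module
tests one locus at a time and ignores linkage between loci.
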
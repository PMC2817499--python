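# rlgsim — virtual restriction landmark genome scanning

`rlgsim` simulates Restriction Landmark Genome Scanning (RLGS) in silico:
methylation-aware digestion of diploid genomes with the
NotI–MspI–BamHI (`[MspI]`) and NotI–HpaII–BamHI (`[HpaII]`) enzyme
combinations, synthesis and comparison of the resulting two-dimensional gel
spot patterns, and per-locus segregation analysis of progeny panels that
flags non-Mendelian inheritance of DNA methylation.

It is written for epigenomics researchers who want to reason quantitatively
about RLGS experiments — which fragments become spots, what a half-intensity
spot implies, how epialleles segregate through crosses — without a gel.

## The method in brief

Every cleavable NotI cut is a radiolabelled landmark. Walking from a
landmark cut in each direction, the first cleavable MspI/HpaII or NotI cut
ends the first-dimension fragment (`len_1d`); the first cleavable BamHI cut
strictly inside that extent ends the second-dimension fragment (`len_2d`,
else the fragment runs on the gel diagonal at `len_2d = len_1d`). Mobility
is a normalized log-linear map per dimension,

    x(L) = (log10 Lmax − log10 L) / (log10 Lmax − log10 Lmin),

with detection windows defaulting to 500–25,000 bp (1D) and 100–5,000 bp (2D).

Methylation enters through cleavability. MspI and HpaII both recognise CCGG
but differ in sensitivity: MspI, not HpaII, cleaves C^mCGG
(internal-cytosine methylation); neither cleaves ^mCCGG or ^mC^mCGG. Hence a
spot present in `[MspI]` but absent (or halved) in `[HpaII]` marks an
internal-C-methylated site, and blocking (outer-C) methylation removes a
spot from both patterns.

Each haplotype contributes an intensity quantum of 0.5 per fragment, so a
locus present on both alleles gives a 1.0 spot and a heterozygous one — in
sequence *or* in methylation — a 0.5 spot. Progeny panels classified as
full/half/absent at a locus are tested against Mendelian expectations
(1:1 for a het-producer × non-producer F1; 1:2:1 for selfing a het) with
exact binomial/multinomial tests and Benjamini–Hochberg correction; a
selfed panel that stays uniformly half-intensity is the canonical
non-Mendelian methylation-maintenance signature.

## Worked example

The packaged fixture mirrors the rice spot-200 geometry: parent N
("Nipponbare-like") carries the spot-defining BamHI site on both alleles and
blocking methylation at the MspI/HpaII (M) site on one; parent K
("Kasalath-like") lacks the BamHI site on both alleles.

```sh
rlgsim run-all --seed 1 --out demo
```

`demo/Nipponbare.MspI.spots.tsv` then contains (columns `len_1d len_2d intensity`):

```
2400  1400  0.5    # the focal spot: N-to-B fragment, heterozygous => half
3000  1400  0.5    # the blocked allele's fragment, NotI-NotI in 1D
1300   800  1.0    # a background locus shared by both alleles
...
```

The focal spot at (2400, 1400) runs at intensity 0.5 — half the modal
(background) intensity of 1.0 — in both `[MspI]` and `[HpaII]`, because
outer-C methylation blocks both enzymes; `demo/Kasalath.MspI.spots.tsv` has
no spot at those coordinates. `demo/N_selfed.segregation.tsv` shows the
maintenance-model selfed panel:

```
locus          combo  n  observed  expected                        test               p        verdict
chr11:10000:+  MspI   9  half:9    absent:0.25;full:0.25;half:0.5  exact_multinomial  0.01009  non_mendelian_flag
```

all nine selfed progeny of the heterozygous parent keep the half-intensity
spot, and the exact multinomial test against the Mendelian 1:2:1 flags the
locus as non-Mendelian. The same stages are available as library calls
(`rlgsim.diploid_pattern`, `rlgsim.msp_hpa_diff`, `rlgsim.flag_non_mendelian`,
`rlgsim.simulate_cross`, …) and as the CLI subcommands `simulate`, `digest`,
`diff`, `segregate`.

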
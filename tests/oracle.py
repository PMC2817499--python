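"""Independent brute-force digestion oracle for cross-checking fragments.

Performs the three-step digestion literally, with its own site scanner and
hard-coded sensitivity rules: cut at every cleavable NotI site; for each
landmark keep the NotI-ended piece up to the neighbouring NotI cut (or the
sequence end); digest that piece with the second enzyme keeping the
NotI-ended sub-piece; digest that with BamHI keeping the NotI-ended
sub-piece.  Shares no code with the package's fragment walker.
"""

RECOGNITION = {"NotI": "GCGGCCGC", "MspI": "CCGG", "HpaII": "CCGG", "BamHI": "GGATCC"}
CUT_OFFSET = {"NotI": 2, "MspI": 1, "HpaII": 1, "BamHI": 1}
BLOCKED = {
    "NotI": {"cpg_methylated"},
    "MspI": {"outer_C", "both_C"},
    "HpaII": {"internal_C", "outer_C", "both_C", "cpg_methylated"},
    "BamHI": set(),
}


def site_starts(seq, recognition):
    out = []
    for i in range(len(seq) - len(recognition) + 1):
        if seq[i : i + len(recognition)] == recognition:
            out.append(i)
    return out


def cleavable_cuts(seq, overlay, enzyme_name):
    """overlay maps site start -> state string for a single chromosome."""
    rec, off = RECOGNITION[enzyme_name], CUT_OFFSET[enzyme_name]
    return [
        s + off
        for s in site_starts(seq, rec)
        if overlay.get(s, "unmethylated") not in BLOCKED[enzyme_name]
    ]


def brute_force_fragments(seq, overlay, second_enzyme, chrom="chr"):
    """All landmark fragments as (chrom, cut, dir, len_1d, kind_1d, len_2d, kind_2d)."""
    noti = cleavable_cuts(seq, overlay, "NotI")
    sec = cleavable_cuts(seq, overlay, second_enzyme)
    bam = cleavable_cuts(seq, overlay, "BamHI")
    fragments = []
    for c in noti:
        # '+' direction: NotI piece runs to the next NotI cut or sequence end.
        later = [x for x in noti if x > c]
        right = later[0] if later else len(seq)
        inside = [s for s in sec if c < s < right]
        if inside:
            end, kind = inside[0], "second_enzyme"
        elif later:
            end, kind = right, "NotI"
        else:
            end, kind = len(seq), "sequence_end"
        if end > c:
            bams = [b for b in bam if c < b < end]
            len_2d = (bams[0] - c) if bams else (end - c)
            kind2 = "BamHI" if bams else "same_as_1d"
            fragments.append((chrom, c, "+", end - c, kind, len_2d, kind2))
        # '-' direction, mirrored.
        earlier = [x for x in noti if x < c]
        left = earlier[-1] if earlier else 0
        inside = [s for s in sec if left < s < c]
        if inside:
            end, kind = inside[-1], "second_enzyme"
        elif earlier:
            end, kind = left, "NotI"
        else:
            end, kind = 0, "sequence_end"
        if c > end:
            bams = [b for b in bam if end < b < c]
            len_2d = (c - bams[-1]) if bams else (c - end)
            kind2 = "BamHI" if bams else "same_as_1d"
            fragments.append((chrom, c, "-", c - end, kind, len_2d, kind2))
    return sorted(fragments)


def random_sequence(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def random_overlay(rng, seq):
    """Random methylation states on a random subset of CCGG and NotI sites."""
    overlay = {}
    for s in site_starts(seq, "CCGG"):
        if rng.random() < 0.4:
            overlay[s] = ["internal_C", "outer_C", "both_C"][int(rng.integers(3))]
    for s in site_starts(seq, "GCGGCCGC"):
        if rng.random() < 0.3:
            overlay[s] = "cpg_methylated"
    return overlay
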
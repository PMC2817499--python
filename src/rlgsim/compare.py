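"""Spot-pattern comparison, intensity classification and methylation calls.

Two comparisons drive the biology:

* sample vs sample (same enzyme combination) -- presence/absence and
  intensity changes between individuals;
* [MspI] vs [HpaII] (same sample) -- a spot present in the [MspI] pattern
  but absent (or halved) in the [HpaII] pattern marks an MspI/HpaII site
  with internal-cytosine methylation (C^mCGG), the only state the two
  isoschizomers resolve.

Matching is done in length-relative terms (default 1%, matching the
co-migration merge tolerance) so it is independent of the gel
parameterisation.  Intensity classes follow the half-intensity heterozygote
rule: a spot at half the baseline intensity means one of the two alleles
does not produce the fragment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional

from .gel import Spot, SpotPattern, relative_close


class IntensityClass(str, Enum):
    ABSENT = "absent"
    HALF = "half"
    FULL = "full"
    OTHER = "other"


@dataclass
class SpotMatch:
    """A matched (or unmatched) spot pair across two patterns."""

    a: Optional[Spot]
    b: Optional[Spot]
    status: str  # 'both' | 'a_only' | 'b_only'
    intensity_ratio: Optional[float] = None

    @property
    def key(self) -> str:
        spot = self.a if self.a is not None else self.b
        chrom, cut, direction, _ = spot.loci[0]
        return f"{chrom}:{cut}:{direction}"


@dataclass
class MethylationCall:
    """Methylation inference for one matched-spot locus.

    ``call`` is one of ``internal_C_methylated`` (spot in [MspI], absent or
    halved in [HpaII]), ``blocked_or_absent`` (spot missing in both patterns
    but expected from a provided genome; outer-C methylation and sequence
    loss are indistinguishable from patterns alone), ``unmethylated``.
    """

    locus: str
    call: str
    zygosity: Optional[str] = None  # 'homozygous' | 'heterozygous' | None
    evidence: Dict[str, float] = field(default_factory=dict)


def match_spots(
    pattern_a: SpotPattern, pattern_b: SpotPattern, tol: float = 0.01
) -> List[SpotMatch]:
    """Greedy nearest-neighbour spot matching within a length tolerance.

    Candidate pairs agree within ``tol`` (relative) in both fragment lengths;
    ties are broken by smaller Euclidean distance in gel coordinates, then by
    smaller ``len_1d``, then by input order, so the result is deterministic.
    Each spot joins at most one match; the rest are reported one-sided.
    """
    if pattern_a.gel != pattern_b.gel:
        raise ValueError("patterns were run on different gel models")
    candidates = []
    for i, sa in enumerate(pattern_a.spots):
        for j, sb in enumerate(pattern_b.spots):
            if relative_close(sa.len_1d, sb.len_1d, tol) and relative_close(
                sa.len_2d, sb.len_2d, tol
            ):
                dist = ((sa.x1 - sb.x1) ** 2 + (sa.x2 - sb.x2) ** 2) ** 0.5
                candidates.append((dist, sa.len_1d, i, j))
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    matches: List[SpotMatch] = []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        sa, sb = pattern_a.spots[i], pattern_b.spots[j]
        matches.append(SpotMatch(sa, sb, "both", sb.intensity / sa.intensity))
    for i, sa in enumerate(pattern_a.spots):
        if i not in used_a:
            matches.append(SpotMatch(sa, None, "a_only"))
    for j, sb in enumerate(pattern_b.spots):
        if j not in used_b:
            matches.append(SpotMatch(None, sb, "b_only"))
    matches.sort(
        key=lambda m: (
            (m.a or m.b).len_1d,
            (m.a or m.b).len_2d,
            m.status,
        )
    )
    return matches


def classify_intensity(
    spot_intensity: float, baseline: float, tol: float = 0.1
) -> IntensityClass:
    """Classify a spot intensity against a full-intensity baseline.

    Bands are relative: ``full`` within ``tol`` of the baseline, ``half``
    within ``tol`` of half the baseline, ``absent`` at zero, ``other``
    elsewhere.  The default 10% tolerance is a modelling choice; the
    original visual judgement of "half the intensity of the surrounding
    spots" carries no stated threshold.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    ratio = spot_intensity / baseline
    if spot_intensity == 0:
        return IntensityClass.ABSENT
    if abs(ratio - 1.0) <= tol:
        return IntensityClass.FULL
    if abs(ratio - 0.5) <= 0.5 * tol:
        return IntensityClass.HALF
    return IntensityClass.OTHER


def modal_intensity(pattern: SpotPattern) -> float:
    """Modal spot intensity: the 'surrounding spots' baseline.

    Ties are broken toward the larger intensity so that a pattern with as
    many heterozygous as homozygous spots still normalises to the
    full-intensity quantum.
    """
    if not pattern.spots:
        raise ValueError("empty pattern has no baseline intensity")
    counts = Counter(s.intensity for s in pattern.spots)
    best = max(counts.values())
    return max(v for v, c in counts.items() if c == best)


def spot_intensity_at(
    pattern: SpotPattern, len_1d: float, len_2d: float, tol: float = 0.01
) -> float:
    """Summed intensity of spots co-migrating with (len_1d, len_2d)."""
    return sum(
        s.intensity
        for s in pattern.spots
        if relative_close(s.len_1d, len_1d, tol) and relative_close(s.len_2d, len_2d, tol)
    )


def msp_hpa_diff(
    pattern_mspI: SpotPattern,
    pattern_hpaII: SpotPattern,
    tol: float = 0.01,
    ratio_tol: float = 0.1,
) -> List[MethylationCall]:
    """Call internal-C methylation from [MspI] vs [HpaII] differences.

    A spot only in [MspI] is an internal-C-methylated site (MspI cleaves
    C^mCGG, HpaII does not); present in both at half the [MspI] intensity is
    a heterozygous internal-C call.  Equal-intensity matches are
    unmethylated at that site and produce no call; sites absent from both
    patterns are not callable from patterns alone and are omitted.
    """
    calls: List[MethylationCall] = []
    for m in match_spots(pattern_mspI, pattern_hpaII, tol):
        if m.status == "a_only":
            calls.append(
                MethylationCall(
                    locus=m.key,
                    call="internal_C_methylated",
                    zygosity="homozygous",
                    evidence={"mspI": m.a.intensity, "hpaII": 0.0},
                )
            )
        elif m.status == "both" and abs(m.intensity_ratio - 0.5) <= 0.5 * ratio_tol:
            calls.append(
                MethylationCall(
                    locus=m.key,
                    call="internal_C_methylated",
                    zygosity="heterozygous",
                    evidence={"mspI": m.a.intensity, "hpaII": m.b.intensity},
                )
            )
    return calls
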
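"""NotI-anchored fragment enumeration and virtual 2D gel spot patterns.

The in silico digest mirrors the physical protocol: every cleavable NotI cut
is a radiolabelled landmark; walking away from it in each direction, the
first cleavable second-enzyme (MspI or HpaII) or NotI cut ends the fragment
seen in the first gel dimension, and the first cleavable BamHI cut strictly
inside that extent ends the fragment seen in the second dimension (a
fragment with no internal BamHI cut runs undigested at ``len_2d == len_1d``,
the gel "diagonal").

A diploid's pattern is the union of its two haplotypes' fragments, each
contributing an intensity quantum of 0.5 so that a locus present on both
alleles shows a full-intensity (1.0) spot and a heterozygous locus a
half-intensity one.  Co-migrating fragments are merged within a relative
length tolerance per dimension.

Gel mobility is a normalized log-linear map per dimension: only relative
spot positions matter for pattern comparison, so no attempt is made to model
Ogston/reptation physics.  Detection windows default to 500-25,000 bp (1D)
and 100-5,000 bp (2D), bracketing typical RLGS agarose/polyacrylamide
resolution; the physical gel dimensions do not determine bp ranges without
calibration, so the windows are configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .enzymes import (
    BAMHI,
    BUILTIN_ENZYMES,
    MSPI,
    NOTI,
    Enzyme,
    Haplotype,
    cleavable_cut_positions,
)


class OutOfWindowError(ValueError):
    """Fragment length outside the gel's detection window."""


@dataclass(frozen=True)
class GelModel:
    """Detection windows (bp) and log-linear mobility map for both dimensions."""

    window_1d: Tuple[int, int] = (500, 25_000)
    window_2d: Tuple[int, int] = (100, 5_000)

    def __post_init__(self) -> None:
        for dim, (lo, hi) in (("1d", self.window_1d), ("2d", self.window_2d)):
            if not 0 < lo < hi:
                raise ValueError(f"window_{dim}: need 0 < min < max, got ({lo}, {hi})")

    def _window(self, dimension: int) -> Tuple[int, int]:
        if dimension == 1:
            return self.window_1d
        if dimension == 2:
            return self.window_2d
        raise ValueError(f"dimension must be 1 or 2, got {dimension}")

    def mobility(self, length: float, dimension: int) -> float:
        """Map a fragment length to a gel coordinate in [0, 1].

        ``x = (log10(Lmax) - log10(L)) / (log10(Lmax) - log10(Lmin))``:
        strictly decreasing in length, 0 at the window maximum and 1 at the
        minimum.  Lengths outside the window raise :class:`OutOfWindowError`.
        """
        lo, hi = self._window(dimension)
        if not lo <= length <= hi:
            raise OutOfWindowError(
                f"length {length} bp outside {dimension}D detection window ({lo}, {hi})"
            )
        return (math.log10(hi) - math.log10(length)) / (math.log10(hi) - math.log10(lo))

    def in_window(self, len_1d: float, len_2d: float) -> bool:
        return (
            self.window_1d[0] <= len_1d <= self.window_1d[1]
            and self.window_2d[0] <= len_2d <= self.window_2d[1]
        )


def mobility(length: float, dimension: int, gel: GelModel) -> float:
    """Functional form of :meth:`GelModel.mobility`."""
    return gel.mobility(length, dimension)


@dataclass(frozen=True)
class RlgsFragment:
    """One landmark-anchored fragment (one NotI cut, one direction).

    ``len_1d`` runs from the landmark to the first cleavable second-enzyme or
    NotI cut (``end_1d_kind``); ``len_2d`` to the first cleavable BamHI cut
    strictly inside the 1D extent, else ``len_2d == len_1d``
    (``end_2d_kind == "same_as_1d"``).
    """

    chrom: str
    landmark_cut: int
    direction: str  # '+' or '-'
    len_1d: int
    end_1d_kind: str  # 'second_enzyme' | 'NotI' | 'sequence_end'
    len_2d: int
    end_2d_kind: str  # 'BamHI' | 'same_as_1d'
    haplotype_id: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.len_2d <= self.len_1d:
            raise ValueError(
                f"fragment {self.locus_key}: need 0 < len_2d <= len_1d, "
                f"got {self.len_2d}, {self.len_1d}"
            )

    @property
    def locus_key(self) -> str:
        return f"{self.chrom}:{self.landmark_cut}:{self.direction}"


def enumerate_fragments(
    hap: Haplotype,
    second_enzyme: Enzyme = MSPI,
    landmark_enzyme: Enzyme = NOTI,
    enzyme_2d: Enzyme = BAMHI,
) -> List[RlgsFragment]:
    """Enumerate both-direction landmark fragments of one haplotype.

    Walking order honours methylation: a blocked site is passed over and the
    walk continues to the next cleavable cut, or to the chromosome boundary
    (``end_1d_kind == "sequence_end"``).
    """
    fragments: List[RlgsFragment] = []
    for chrom in sorted(hap.sequences):
        length = len(hap.sequences[chrom])
        if length == 0:
            continue
        landmarks = cleavable_cut_positions(hap, chrom, landmark_enzyme)
        if landmarks.size == 0:
            continue
        second = cleavable_cut_positions(hap, chrom, second_enzyme)
        bam = cleavable_cut_positions(hap, chrom, enzyme_2d)
        second_set = set(second.tolist())
        ends = np.unique(np.concatenate([second, landmarks]))
        for cut in landmarks.tolist():
            frag = _walk(chrom, cut, "+", ends, second_set, bam, length, hap.id)
            if frag is not None:
                fragments.append(frag)
            frag = _walk(chrom, cut, "-", ends, second_set, bam, length, hap.id)
            if frag is not None:
                fragments.append(frag)
    fragments.sort(key=lambda f: (f.chrom, f.landmark_cut, f.direction))
    return fragments


def _walk(
    chrom: str,
    cut: int,
    direction: str,
    ends: np.ndarray,
    second_set: set,
    bam: np.ndarray,
    chrom_len: int,
    hap_id: str,
) -> Optional[RlgsFragment]:
    if direction == "+":
        i = int(np.searchsorted(ends, cut, side="right"))
        if i < ends.size:
            end = int(ends[i])
            kind = "second_enzyme" if end in second_set else "NotI"
        else:
            end, kind = chrom_len, "sequence_end"
        len_1d = end - cut
        if len_1d <= 0:
            return None
        j = int(np.searchsorted(bam, cut, side="right"))
        if j < bam.size and bam[j] < end:
            len_2d, kind2 = int(bam[j]) - cut, "BamHI"
        else:
            len_2d, kind2 = len_1d, "same_as_1d"
    else:
        i = int(np.searchsorted(ends, cut, side="left")) - 1
        if i >= 0:
            end = int(ends[i])
            kind = "second_enzyme" if end in second_set else "NotI"
        else:
            end, kind = 0, "sequence_end"
        len_1d = cut - end
        if len_1d <= 0:
            return None
        j = int(np.searchsorted(bam, cut, side="left")) - 1
        if j >= 0 and bam[j] > end:
            len_2d, kind2 = cut - int(bam[j]), "BamHI"
        else:
            len_2d, kind2 = len_1d, "same_as_1d"
    return RlgsFragment(chrom, cut, direction, len_1d, kind, len_2d, kind2, hap_id)


#: A spot's contributing locus: (chrom, landmark_cut, direction, haplotype id).
Locus = Tuple[str, int, str, str]


@dataclass(frozen=True)
class Spot:
    """One gel spot: 2D coordinates, fragment lengths, summed intensity, loci."""

    x1: float
    x2: float
    len_1d: int
    len_2d: int
    intensity: float
    loci: Tuple[Locus, ...]


@dataclass
class SpotPattern:
    """All spots of one sample under one enzyme combination ([MspI]/[HpaII])."""

    sample_id: str
    combo: str
    spots: List[Spot]
    gel: GelModel

    @property
    def total_intensity(self) -> float:
        return sum(s.intensity for s in self.spots)

    def intensities(self) -> List[float]:
        return [s.intensity for s in self.spots]


#: Per-haplotype intensity quantum: one allele of one locus.
INTENSITY_QUANTUM = 0.5


def _resolve_combo(combo: Union[str, Enzyme]) -> Enzyme:
    if isinstance(combo, Enzyme):
        return combo
    try:
        enz = BUILTIN_ENZYMES[combo]
    except KeyError:
        raise ValueError(f"unknown enzyme combination {combo!r}") from None
    if enz.recognition != MSPI.recognition:
        raise ValueError(f"{combo!r} is not an MspI/HpaII isoschizomer")
    return enz


def relative_close(a: float, b: float, tol: float) -> bool:
    """Relative length agreement: |a - b| <= tol * max(a, b)."""
    return abs(a - b) <= tol * max(a, b)


def _contributions(
    haps: Sequence[Haplotype],
    second: Enzyme,
    gel: GelModel,
    include_sequence_end: bool,
    include_diagonal: bool,
) -> List[Tuple[int, int, Locus]]:
    out: List[Tuple[int, int, Locus]] = []
    for hap in haps:
        for frag in enumerate_fragments(hap, second):
            if frag.end_1d_kind == "sequence_end" and not include_sequence_end:
                continue
            if frag.end_2d_kind == "same_as_1d" and not include_diagonal:
                continue
            if not gel.in_window(frag.len_1d, frag.len_2d):
                continue
            out.append(
                (frag.len_1d, frag.len_2d,
                 (frag.chrom, frag.landmark_cut, frag.direction, hap.id))
            )
    return out


def _merge(
    contribs: List[Tuple[int, int, Locus]], gel: GelModel, tol: float
) -> List[Spot]:
    """Single-linkage merge of co-migrating contributions.

    Contributions whose lengths agree within ``tol`` (relative, both
    dimensions) fall into one spot; the representative lengths are those of
    the first member in (chrom, landmark_cut, direction, haplotype) order,
    which makes the merge deterministic.
    """
    order = sorted(contribs, key=lambda c: c[2])
    n = len(order)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if relative_close(order[i][0], order[j][0], tol) and relative_close(
                order[i][1], order[j][1], tol
            ):
                parent[find(j)] = find(i)

    clusters: Dict[int, List[Tuple[int, int, Locus]]] = {}
    for i, c in enumerate(order):
        clusters.setdefault(find(i), []).append(c)

    spots = []
    for members in clusters.values():
        rep_1d, rep_2d, _ = members[0]
        spots.append(
            Spot(
                x1=gel.mobility(rep_1d, 1),
                x2=gel.mobility(rep_2d, 2),
                len_1d=rep_1d,
                len_2d=rep_2d,
                intensity=INTENSITY_QUANTUM * len(members),
                loci=tuple(m[2] for m in members),
            )
        )
    spots.sort(key=lambda s: (s.len_1d, s.len_2d, s.loci))
    return spots


def haplotype_pattern(
    hap: Haplotype,
    combo: Union[str, Enzyme],
    gel: GelModel = GelModel(),
    sample_id: Optional[str] = None,
    merge_tol: float = 0.01,
    include_sequence_end: bool = False,
    include_diagonal: bool = True,
) -> SpotPattern:
    """Spot pattern of a single haplotype (each fragment contributes 0.5).

    ``sequence_end`` fragments are excluded by default: physical chromosome
    ends are ddNTP-blocked before labelling and shear ends are unknowable in
    silico.  Fragments without an internal BamHI cut are retained on the gel
    diagonal by default, as in-gel digestion leaves them intact.
    """
    second = _resolve_combo(combo)
    contribs = _contributions([hap], second, gel, include_sequence_end, include_diagonal)
    return SpotPattern(
        sample_id=sample_id or hap.id,
        combo=second.name,
        spots=_merge(contribs, gel, merge_tol),
        gel=gel,
    )


def diploid_pattern(
    hap_a: Haplotype,
    hap_b: Haplotype,
    combo: Union[str, Enzyme],
    gel: GelModel = GelModel(),
    sample_id: Optional[str] = None,
    merge_tol: float = 0.01,
    include_sequence_end: bool = False,
    include_diagonal: bool = True,
) -> SpotPattern:
    """Spot pattern of a diploid individual.

    The union of the two haplotype patterns with co-migration merging: a
    locus producing the same fragment from both alleles yields intensity
    1.0, a heterozygous one 0.5.
    """
    second = _resolve_combo(combo)
    contribs = _contributions(
        [hap_a, hap_b], second, gel, include_sequence_end, include_diagonal
    )
    return SpotPattern(
        sample_id=sample_id or f"{hap_a.id}/{hap_b.id}",
        combo=second.name,
        spots=_merge(contribs, gel, merge_tol),
        gel=gel,
    )
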
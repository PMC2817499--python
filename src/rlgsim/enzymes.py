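"""Restriction enzymes, recognition-site scanning and methylation-aware cleavage.

RLGS profiles a genome with three sequential digests: a rare-cutting,
CpG-containing "landmark" enzyme (NotI), a frequent second enzyme that is one
of the isoschizomer pair MspI/HpaII (both recognise CCGG but differ in
methylation sensitivity), and an in-gel third enzyme (BamHI).  The whole
method turns on which recognition sites are actually cleavable given the
cytosine-methylation state of each site:

* ``C^mCGG`` (internal cytosine methylated) -- MspI cleaves, HpaII does not.
* ``^mCCGG`` and ``^mC^mCGG`` (outer or both cytosines) -- neither cleaves.
* NotI is blocked by CpG methylation within its GCGGCCGC site.

This module holds the enzyme definitions (built-in and user-configurable),
IUPAC-aware site scanning, the methylation-state vocabulary, and the
``Haplotype`` container binding a named sequence set to a per-site
methylation overlay.

Coordinates are 0-based, half-open throughout; a "cut position" is the
top-strand cut coordinate (``site start + cut_offset``).  Fragment lengths
are differences of cut positions; the few-nucleotide overhang asymmetry is
far below gel resolution and is ignored.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement


class MethylationState(str, Enum):
    """Cytosine-methylation state of one recognition site on one haplotype.

    ``INTERNAL_C``/``OUTER_C``/``BOTH_C`` describe CCGG sites (C^mCGG, ^mCCGG,
    ^mC^mCGG); ``CPG_METHYLATED`` describes methylation of the CpG inside a
    non-CCGG site such as NotI's.  Unannotated sites are ``UNMETHYLATED``.
    """

    UNMETHYLATED = "unmethylated"
    INTERNAL_C = "internal_C"
    OUTER_C = "outer_C"
    BOTH_C = "both_C"
    CPG_METHYLATED = "cpg_methylated"


#: IUPAC nucleotide codes accepted in recognition sequences and genomes.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

_SEQ_RE = re.compile(r"[^ACGTRYSWKMBDHVN]")


def _validate_nucleotides(sequence: str, what: str) -> None:
    m = _SEQ_RE.search(sequence)
    if m:
        raise ValueError(
            f"{what} contains non-IUPAC character {m.group()!r} at position {m.start()}"
        )


@dataclass
class Enzyme:
    """A restriction enzyme: recognition site, cut offset and sensitivity table.

    Parameters
    ----------
    name : str
        Enzyme name, e.g. ``"MspI"``.
    recognition : str
        IUPAC recognition sequence (top strand).
    cut_offset : int
        0-based top-strand cut position within the recognition window.
    sensitivity : mapping
        ``MethylationState -> bool`` (True = the enzyme cleaves a site in
        that state).  Must cover every defined state.
    """

    name: str
    recognition: str
    cut_offset: int
    sensitivity: Mapping[MethylationState, bool]

    def __post_init__(self) -> None:
        self.recognition = self.recognition.upper()
        if not self.recognition:
            raise ValueError(f"enzyme {self.name}: empty recognition sequence")
        _validate_nucleotides(self.recognition, f"enzyme {self.name} recognition")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"enzyme {self.name}: cut_offset {self.cut_offset} outside "
                f"recognition window of length {len(self.recognition)}"
            )
        missing = [s for s in MethylationState if s not in self.sensitivity]
        if missing:
            raise ValueError(
                f"enzyme {self.name}: sensitivity table missing states "
                + ", ".join(s.value for s in missing)
            )

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)

    def cleaves(self, state: MethylationState) -> bool:
        """Whether this enzyme cuts a site carrying ``state``."""
        try:
            return bool(self.sensitivity[state])
        except KeyError:
            raise ValueError(
                f"enzyme {self.name}: no sensitivity entry for state {state!r}"
            ) from None


def enzyme(
    name: str,
    recognition: str,
    cut_offset: int,
    blocked: Iterable[MethylationState] = (),
) -> Enzyme:
    """Build an :class:`Enzyme` from the set of states that block it."""
    blocked = frozenset(blocked)
    table = {s: s not in blocked for s in MethylationState}
    return Enzyme(name, recognition, cut_offset, table)


# Built-in enzymes of the NotI-MspI/HpaII-BamHI combinations.  NotI is treated
# as methylation-sensitive (blocked by CpG methylation of its site), the role
# it plays as a landmark in methylation-survey RLGS; overlays that never
# annotate NotI sites leave it effectively insensitive.
NOTI = enzyme("NotI", "GCGGCCGC", 2, blocked={MethylationState.CPG_METHYLATED})
MSPI = enzyme(
    "MspI", "CCGG", 1,
    blocked={MethylationState.OUTER_C, MethylationState.BOTH_C},
)
HPAII = enzyme(
    "HpaII", "CCGG", 1,
    blocked={
        MethylationState.INTERNAL_C,
        MethylationState.OUTER_C,
        MethylationState.BOTH_C,
        MethylationState.CPG_METHYLATED,
    },
)
BAMHI = enzyme("BamHI", "GGATCC", 1, blocked=())

BUILTIN_ENZYMES: Dict[str, Enzyme] = {
    e.name: e for e in (NOTI, MSPI, HPAII, BAMHI)
}


def load_enzymes(path) -> Dict[str, Enzyme]:
    """Read enzyme definitions from a TSV config file.

    Columns: ``name``, ``recognition``, ``cut_offset``, ``blocked`` (comma
    separated :class:`MethylationState` values, or ``-`` for none).
    """
    out: Dict[str, Enzyme] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        required = {"name", "recognition", "cut_offset", "blocked"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: enzyme config needs columns {sorted(required)}"
            )
        for i, row in enumerate(reader, start=2):
            blocked_field = row["blocked"].strip()
            blocked = (
                [MethylationState(s.strip()) for s in blocked_field.split(",")]
                if blocked_field not in ("", "-")
                else []
            )
            try:
                out[row["name"]] = enzyme(
                    row["name"], row["recognition"], int(row["cut_offset"]), blocked
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from exc
    return out


@dataclass
class SiteMatch:
    """One recognition-site occurrence on a chromosome.

    ``start`` is 0-based; the window is ``[start, start + len(recognition))``.
    ``cut_pos`` is the top-strand cut coordinate.  ``strand`` is ``'-'`` for
    matches of a non-palindromic site found on the reverse strand (reported
    in forward coordinates).
    """

    chrom: str
    start: int
    enzyme: str
    cut_pos: int
    state: MethylationState = MethylationState.UNMETHYLATED
    strand: str = "+"


def _iupac_class(code: str) -> str:
    bases = ambiguous_dna_values[code]
    return bases if len(bases) == 1 else f"[{bases}]"


@lru_cache(maxsize=None)
def _site_pattern(recognition: str) -> "re.Pattern[str]":
    # Lookahead so overlapping occurrences are all reported.
    return re.compile("(?=" + "".join(_iupac_class(c) for c in recognition) + ")")


@lru_cache(maxsize=None)
def _anchored_pattern(recognition: str) -> "re.Pattern[str]":
    return re.compile("".join(_iupac_class(c) for c in recognition))


@lru_cache(maxsize=512)
def _scan(sequence: str, recognition: str) -> Tuple[int, ...]:
    """Start positions of (possibly overlapping) forward-strand matches."""
    return tuple(m.start() for m in _site_pattern(recognition).finditer(sequence))


def find_sites(sequence: str, enz: Enzyme, chrom: str = "seq") -> List[SiteMatch]:
    """Scan a chromosome sequence for recognition sites of one enzyme.

    Palindromic sites (all four built-in enzymes) are scanned on the forward
    strand only; non-palindromic sites are scanned on both strands, with
    reverse-strand hits reported in forward coordinates.  Overlapping matches
    are each reported; positions ascend.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    _validate_nucleotides(sequence, f"sequence {chrom!r}")
    k = len(enz.recognition)
    sites = [
        SiteMatch(chrom, s, enz.name, s + enz.cut_offset)
        for s in _scan(sequence, enz.recognition)
    ]
    if not enz.is_palindromic:
        rc = reverse_complement(enz.recognition)
        sites += [
            SiteMatch(chrom, s, enz.name, s + k - enz.cut_offset, strand="-")
            for s in _scan(sequence, rc)
        ]
        sites.sort(key=lambda m: (m.start, m.strand))
    return sites


def is_cleavable(
    site: SiteMatch,
    enz: Enzyme,
    registry: Optional[Mapping[str, Enzyme]] = None,
) -> bool:
    """Whether ``enz`` cuts ``site`` given the site's methylation state.

    The site may have been located by an isoschizomer (MspI and HpaII share
    CCGG); enzymes with a different recognition sequence are rejected.
    """
    registry = BUILTIN_ENZYMES if registry is None else registry
    located_by = registry.get(site.enzyme)
    if located_by is not None and located_by.recognition != enz.recognition:
        raise ValueError(
            f"site found by {site.enzyme} ({located_by.recognition}) is not "
            f"compatible with {enz.name} ({enz.recognition})"
        )
    return enz.cleaves(site.state)


@dataclass
class Haplotype:
    """A named sequence set plus a per-site methylation overlay.

    ``overlay`` maps ``(chrom, site start)`` to a :class:`MethylationState`;
    positions absent from the overlay are unmethylated.  ``meta`` carries
    provenance (e.g. planted-locus bookkeeping from the simulator) and does
    not take part in equality.
    """

    id: str
    sequences: Dict[str, str]
    overlay: Dict[Tuple[str, int], MethylationState] = field(default_factory=dict)
    meta: dict = field(default_factory=dict, compare=False)

    def state_at(self, chrom: str, start: int) -> MethylationState:
        return self.overlay.get((chrom, start), MethylationState.UNMETHYLATED)

    def validate(self, enzymes: Iterable[Enzyme] = ()) -> "Haplotype":
        """Check that every overlay position sits on a recognition site.

        ``enzymes`` defaults to the built-in set.  Raises ``ValueError`` on
        the first offending overlay entry.
        """
        enzymes = list(enzymes) or list(BUILTIN_ENZYMES.values())
        for (chrom, start), state in self.overlay.items():
            if chrom not in self.sequences:
                raise ValueError(f"overlay chromosome {chrom!r} not in sequences")
            seq = self.sequences[chrom]
            if not 0 <= start < len(seq):
                raise ValueError(f"overlay position {chrom}:{start} out of range")
            if not isinstance(state, MethylationState):
                raise ValueError(f"overlay {chrom}:{start}: bad state {state!r}")
            if not any(_matches_at(seq, start, e) for e in enzymes):
                raise ValueError(
                    f"overlay position {chrom}:{start} does not coincide with a "
                    "recognition site of any configured enzyme"
                )
        return self


def _matches_at(seq: str, start: int, enz: Enzyme) -> bool:
    window = seq[start : start + len(enz.recognition)]
    if len(window) < len(enz.recognition):
        return False
    if _anchored_pattern(enz.recognition).fullmatch(window):
        return True
    if not enz.is_palindromic and _anchored_pattern(
        reverse_complement(enz.recognition)
    ).fullmatch(window):
        return True
    return False


def cleavable_cut_positions(hap: Haplotype, chrom: str, enz: Enzyme) -> np.ndarray:
    """Sorted unique top-strand cut positions of cleavable ``enz`` sites.

    Site scanning is cached per (sequence, recognition); the haplotype's
    overlay then vetoes blocked sites.  Overlapping sites are independent:
    a blocked site never masks a cleavable overlapping one.
    """
    seq = hap.sequences[chrom]
    if not seq:
        return np.empty(0, dtype=np.int64)
    starts = _scan(seq, enz.recognition)
    k = len(enz.recognition)
    cuts = set(s + enz.cut_offset for s in starts)
    rc_starts: Tuple[int, ...] = ()
    if not enz.is_palindromic:
        rc_starts = _scan(seq, reverse_complement(enz.recognition))
        cuts.update(s + k - enz.cut_offset for s in rc_starts)
    if hap.overlay:
        start_set = set(starts)
        rc_set = set(rc_starts)
        for (c, s), state in hap.overlay.items():
            if c != chrom or enz.cleaves(state):
                continue
            if s in start_set:
                cuts.discard(s + enz.cut_offset)
            if s in rc_set:
                cuts.discard(s + k - enz.cut_offset)
    return np.array(sorted(cuts), dtype=np.int64)
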
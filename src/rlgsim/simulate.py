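"""Synthetic genomes, epialleles and simulated crosses.

The generator embeds a controlled restriction-site layout in random
background sequence and simulates crosses under configurable epigenetic
transmission models.  The packaged fixture reproduces the geometry of the
rice spot-200 locus: a NotI landmark (N), a BamHI site (B) 1,400 bp
downstream, an MspI/HpaII site (M) 2,400 bp downstream, and the next NotI
site 3,000 bp downstream, so the unmethylated allele runs at
(len_1d, len_2d) = (2400, 1400).  The Nipponbare-like parent carries the B
site on both alleles and blocking (outer-cytosine) methylation at M on one;
the Kasalath-like parent lacks the B site on both alleles and is
unmethylated, so it never produces the focal spot.

Transmission models:

* ``mendelian`` -- each parent transmits one of its two (allele, epiallele)
  pairs with probability 1/2, independently per individual.
* ``maintain_heterozygous`` -- allele transmission is Mendelian, but in any
  progeny carrying the focal parent's spot-capable allele the M-site
  methylation is re-established so the individual reproduces the parent's
  half-intensity configuration (with the model's maintenance probability).
  This is a phenomenological stand-in for the observed behaviour of selfed
  progeny, not a mechanistic claim: pattern data cannot distinguish
  maintenance from re-establishment.
* ``demethylate_progeny`` -- transmitted focal epialleles are erased.

Everything is reproducible byte-for-byte from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .enzymes import (
    BAMHI,
    MSPI,
    NOTI,
    Haplotype,
    MethylationState,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# Recognition strings screened for during background generation.
_PLANT_RECOGNITIONS = (NOTI.recognition, MSPI.recognition, BAMHI.recognition)
# Ablation candidates for the B-absent allele: single-base variants of the
# BamHI site tried in order until one creates no new recognition site.
_B_ABLATIONS = ("GGATCA", "GGATCT", "GGATTC", "GAATCC", "GGCTCC")


@dataclass(frozen=True)
class LocusSpec:
    """Planted restriction-site layout around one NotI landmark.

    Offsets are distances between top-strand *cut* positions, so they equal
    the fragment lengths the locus produces: ``msp_offset`` is the
    unmethylated allele's 1D length and ``bam_offset`` its 2D length.
    ``bam_offset`` of None plants no BamHI site (the fragment runs on the
    diagonal); ``next_notI_offset`` of None plants no second landmark.
    """

    name: str
    chrom: str
    notI_cut: int
    msp_offset: int
    bam_offset: Optional[int] = None
    next_notI_offset: Optional[int] = None
    guard: int = 100

    def __post_init__(self) -> None:
        if self.msp_offset <= 0:
            raise ValueError(f"{self.name}: msp_offset must be positive")
        windows = self.site_windows()
        spans = sorted((w[0], w[1]) for w in windows)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.name}: planted site windows overlap ([{s1},{e1}) and [{s2},{e2}))"
                )
        if spans[0][0] - self.guard < 0:
            raise ValueError(f"{self.name}: locus too close to sequence start")

    def site_windows(self) -> List[Tuple[int, int, str, str]]:
        """(start, end, role, recognition) of every planted site."""
        n = self.notI_cut
        out = [
            (n - NOTI.cut_offset, n - NOTI.cut_offset + 8, "NotI", NOTI.recognition),
            (
                n + self.msp_offset - MSPI.cut_offset,
                n + self.msp_offset - MSPI.cut_offset + 4,
                "MspI",
                MSPI.recognition,
            ),
        ]
        if self.bam_offset is not None:
            if not 0 < self.bam_offset < self.msp_offset:
                raise ValueError(
                    f"{self.name}: bam_offset must lie strictly between the landmark "
                    "and the MspI site"
                )
            out.append(
                (
                    n + self.bam_offset - BAMHI.cut_offset,
                    n + self.bam_offset - BAMHI.cut_offset + 6,
                    "BamHI",
                    BAMHI.recognition,
                )
            )
        if self.next_notI_offset is not None:
            if self.next_notI_offset <= self.msp_offset:
                raise ValueError(
                    f"{self.name}: next_notI_offset must lie beyond the MspI site"
                )
            out.append(
                (
                    n + self.next_notI_offset - NOTI.cut_offset,
                    n + self.next_notI_offset - NOTI.cut_offset + 8,
                    "NotI2",
                    NOTI.recognition,
                )
            )
        return out

    @property
    def m_start(self) -> int:
        return self.notI_cut + self.msp_offset - MSPI.cut_offset

    @property
    def protected_interval(self) -> Tuple[int, int]:
        windows = self.site_windows()
        return (
            min(w[0] for w in windows) - self.guard,
            max(w[1] for w in windows) + self.guard,
        )


@dataclass(frozen=True)
class LocusVariant:
    """Per-haplotype allele of a planted locus."""

    b_present: bool = True
    m_state: MethylationState = MethylationState.UNMETHYLATED


@dataclass(frozen=True)
class TransmissionModel:
    name: str
    maintenance_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("mendelian", "maintain_heterozygous", "demethylate_progeny"):
            raise ValueError(f"unknown transmission model {self.name!r}")
        if not 0.0 <= self.maintenance_prob <= 1.0:
            raise ValueError("maintenance_prob must lie in [0, 1]")


MENDELIAN = TransmissionModel("mendelian")
MAINTAIN_HETEROZYGOUS = TransmissionModel("maintain_heterozygous")
DEMETHYLATE_PROGENY = TransmissionModel("demethylate_progeny")


@dataclass
class DiploidIndividual:
    id: str
    haplotypes: Tuple[Haplotype, Haplotype]


@dataclass
class CrossPanel:
    """Progeny of one cross, reproducible from (parents, model, seed)."""

    panel_id: str
    mother_id: str
    father_id: str
    n: int
    seed: int
    model: TransmissionModel
    individuals: List[DiploidIndividual]


def _find_exact(segment: str, recognition: str) -> List[int]:
    out, i = [], segment.find(recognition)
    while i != -1:
        out.append(i)
        i = segment.find(recognition, i + 1)
    return out


def _unintended_hits(
    seq: np.ndarray, lo: int, hi: int, planted_starts: set
) -> List[Tuple[int, int]]:
    """(start, length) of recognition matches in [lo, hi) not planted there."""
    lo = max(lo, 0)
    hi = min(hi, seq.size)
    segment = seq[lo:hi].tobytes().decode()
    hits = []
    for rec in _PLANT_RECOGNITIONS:
        for i in _find_exact(segment, rec):
            if lo + i not in planted_starts:
                hits.append((lo + i, len(rec)))
    return hits


def build_genome(
    specs: Sequence[LocusSpec],
    background_length: int,
    seed: int,
    hap_id: str = "hap",
    variants: Optional[Mapping[str, LocusVariant]] = None,
) -> Haplotype:
    """Plant one or more loci in random background and return a Haplotype.

    Background bases are uniform A/C/G/T.  Within a guard distance of each
    locus's planted sites, accidental NotI/MspI/BamHI recognition sites are
    rewritten (resampled) so the locus geometry is exact; elsewhere
    accidental sites are kept and form the shared background pattern.  All
    random draws depend only on ``(specs, background_length, seed)``, never
    on the variants, so haplotypes built with the same seed share their
    background byte-for-byte.
    """
    variants = dict(variants or {})
    by_chrom: Dict[str, List[LocusSpec]] = {}
    for spec in specs:
        by_chrom.setdefault(spec.chrom, []).append(spec)

    rng = np.random.default_rng(seed)
    sequences: Dict[str, str] = {}
    overlay: Dict[Tuple[str, int], MethylationState] = {}
    meta_loci: Dict[str, dict] = {}

    for chrom in sorted(by_chrom):
        chrom_specs = sorted(by_chrom[chrom], key=lambda s: s.notI_cut)
        seq = _BASES[rng.integers(0, 4, background_length)].copy()
        planted: Dict[int, str] = {}  # start -> recognition
        for spec in chrom_specs:
            for start, end, _, rec in spec.site_windows():
                if end > background_length:
                    raise ValueError(
                        f"{spec.name}: planted site [{start},{end}) exceeds "
                        f"background length {background_length}"
                    )
                planted[start] = rec
        for start, rec in planted.items():
            seq[start : start + len(rec)] = np.frombuffer(rec.encode(), dtype="S1")
        planted_positions = {
            p for start, rec in planted.items() for p in range(start, start + len(rec))
        }
        planted_starts = set(planted)
        # Screen each protected interval until free of accidental sites.
        for spec in chrom_specs:
            lo, hi = spec.protected_interval
            for _ in range(200):
                hits = _unintended_hits(seq, lo, hi, planted_starts)
                if not hits:
                    break
                for start, k in hits:
                    for pos in range(start, start + k):
                        if pos not in planted_positions:
                            seq[pos] = _BASES[rng.integers(0, 4)]
            else:
                raise RuntimeError(
                    f"{spec.name}: could not clear accidental sites near the locus"
                )
        # Apply allele variants (no randomness from here on).
        for spec in chrom_specs:
            variant = variants.get(spec.name, LocusVariant())
            if not variant.b_present:
                if spec.bam_offset is None:
                    raise ValueError(
                        f"{spec.name}: b_present=False but the spec plants no BamHI site"
                    )
                b_start = spec.notI_cut + spec.bam_offset - BAMHI.cut_offset
                remaining = planted_starts - {b_start}
                for candidate in _B_ABLATIONS:
                    seq[b_start : b_start + 6] = np.frombuffer(
                        candidate.encode(), dtype="S1"
                    )
                    lo, hi = spec.protected_interval
                    if not _unintended_hits(seq, lo, hi, remaining):
                        break
                else:
                    raise RuntimeError(
                        f"{spec.name}: no clean BamHI ablation found"
                    )
            if variant.m_state != MethylationState.UNMETHYLATED:
                overlay[(chrom, spec.m_start)] = variant.m_state
            meta_loci[spec.name] = {
                "chrom": chrom,
                "notI_cut": spec.notI_cut,
                "m_site": (chrom, spec.m_start),
                "b_present": variant.b_present,
                "spot_capable": variant.b_present,
                "m_state": variant.m_state.value,
            }
        sequences[chrom] = seq.tobytes().decode()

    hap = Haplotype(
        id=hap_id,
        sequences=sequences,
        overlay=overlay,
        meta={"loci": meta_loci, "background_seed": int(seed)},
    )
    return hap.validate()


def build_locus(
    spec: LocusSpec,
    background_length: int,
    seed: int,
    hap_id: str = "hap",
    b_present: bool = True,
    m_state: MethylationState = MethylationState.UNMETHYLATED,
) -> Haplotype:
    """Single-locus convenience wrapper over :func:`build_genome`."""
    return build_genome(
        [spec],
        background_length,
        seed,
        hap_id=hap_id,
        variants={spec.name: LocusVariant(b_present=b_present, m_state=m_state)},
    )


def _inherit(hap: Haplotype, new_id: str, source_parent: str) -> Haplotype:
    """Copy of a parental haplotype for a progeny (sequences shared)."""
    return Haplotype(
        id=new_id,
        sequences=hap.sequences,
        overlay=dict(hap.overlay),
        meta={**hap.meta, "source_parent": source_parent, "source_hap": hap.id},
    )


def _focal_locus_name(parent: DiploidIndividual, model: TransmissionModel) -> Optional[str]:
    loci = parent.haplotypes[0].meta.get("loci", {})
    if model.name == "mendelian":
        return None
    # The focal locus is the one at which the parent is epiheterozygous, or
    # the single planted locus if none is.
    het = [
        name
        for name in loci
        if parent.haplotypes[0].overlay.get(tuple(loci[name]["m_site"]))
        != parent.haplotypes[1].overlay.get(tuple(loci[name]["m_site"]))
    ]
    if len(het) == 1:
        return het[0]
    if len(loci) == 1:
        return next(iter(loci))
    raise ValueError(
        f"cannot identify a unique focal locus for model {model.name!r}; "
        "parent is epiheterozygous at " + (", ".join(het) or "no locus")
    )


def simulate_cross(
    mother: DiploidIndividual,
    father: DiploidIndividual,
    n: int,
    model: TransmissionModel = MENDELIAN,
    seed: int = 0,
    panel_id: Optional[str] = None,
    focal_parent: Optional[str] = None,
) -> CrossPanel:
    """Simulate ``n`` progeny of a cross under a transmission model.

    ``focal_parent`` (defaults to the mother; for selfing the two coincide)
    names the parent whose epiallele configuration the maintenance model
    re-establishes.
    """
    if n < 0:
        raise ValueError("panel size must be non-negative")
    panel_id = panel_id or f"{mother.id}x{father.id}"
    focal_parent = focal_parent or mother.id
    rng = np.random.default_rng(seed)
    focal = mother if focal_parent == mother.id else father
    locus_name = _focal_locus_name(focal, model)
    if locus_name is not None:
        locus = focal.haplotypes[0].meta["loci"][locus_name]
        m_site = tuple(locus["m_site"])
        blocking = [
            h.overlay[m_site] for h in focal.haplotypes if m_site in h.overlay
        ]
        block_state = blocking[0] if blocking else None

    individuals: List[DiploidIndividual] = []
    for i in range(n):
        mi = int(rng.integers(2))
        fi = int(rng.integers(2))
        ind_id = f"{panel_id}.{i + 1}"
        hm = _inherit(mother.haplotypes[mi], f"{ind_id}.m", mother.id)
        hf = _inherit(father.haplotypes[fi], f"{ind_id}.p", father.id)
        haps = (hm, hf)
        if model.name == "maintain_heterozygous":
            u = rng.random()
            capable = [
                h
                for h in haps
                if h.meta.get("source_parent") == focal_parent
                and h.meta["loci"][locus_name]["spot_capable"]
            ]
            if capable and u < model.maintenance_prob and block_state is not None:
                if len(capable) >= 2:
                    capable[0].overlay[m_site] = block_state
                    for h in capable[1:]:
                        h.overlay.pop(m_site, None)
                else:
                    capable[0].overlay.pop(m_site, None)
        elif model.name == "demethylate_progeny":
            for h in haps:
                h.overlay.pop(m_site, None)
        individuals.append(DiploidIndividual(ind_id, haps))
    return CrossPanel(panel_id, mother.id, father.id, n, int(seed), model, individuals)


# --- packaged Nipponbare/Kasalath-like fixture -----------------------------

#: Focal locus with the spot-200 geometry: fragment between the N and B cuts
#: is the 2D spot (1,400 bp); N-to-M is the 1D fragment (2,400 bp).
SPOT200_SPEC = LocusSpec(
    name="spot200",
    chrom="chr11",
    notI_cut=10_000,
    bam_offset=1_400,
    msp_offset=2_400,
    next_notI_offset=3_000,
)

#: Filler landmark loci shared by every haplotype.  They give the pattern a
#: population of deterministic full-intensity background spots, the
#: "surrounding spots" against which halved intensity is judged.
FILLER_SPECS: Tuple[LocusSpec, ...] = (
    LocusSpec("bg1", "chr11", 30_000, 700),
    LocusSpec("bg2", "chr11", 45_000, 900, bam_offset=500),
    LocusSpec("bg3", "chr11", 60_000, 1_100),
    LocusSpec("bg4", "chr11", 75_000, 1_300, bam_offset=800),
    LocusSpec("bg5", "chr11", 90_000, 1_600),
    LocusSpec("bg6", "chr11", 105_000, 1_900, bam_offset=1_100),
)

FIXTURE_BACKGROUND_LENGTH = 120_000


@dataclass
class Fixture:
    """The packaged two-parent fixture and its simulated cross panels."""

    parent_n: DiploidIndividual
    parent_k: DiploidIndividual
    panels: Dict[str, CrossPanel]
    focal_spec: LocusSpec
    seed: int

    @property
    def focal_len_1d(self) -> int:
        return self.focal_spec.msp_offset

    @property
    def focal_len_2d(self) -> int:
        return self.focal_spec.bam_offset

    @property
    def parent_n_genotype(self) -> Tuple[bool, bool]:
        """Per-allele spot production of the Nipponbare-like parent."""
        return (True, False)

    @property
    def parent_k_genotype(self) -> Tuple[bool, bool]:
        return (False, False)


def _child_seeds(seed: int, k: int) -> List[int]:
    state = np.random.SeedSequence(seed).generate_state(k)
    return [int(s) & 0x7FFFFFFF for s in state]


def nipponbare_kasalath_fixture(
    seed: int = 0,
    n_f1: int = 9,
    n_selfed_n: int = 9,
    n_selfed_k: int = 4,
    f1_model: TransmissionModel = MENDELIAN,
    selfed_model: TransmissionModel = MAINTAIN_HETEROZYGOUS,
    background_length: int = FIXTURE_BACKGROUND_LENGTH,
) -> Fixture:
    """Build the two parents and their reciprocal-F1 and selfed panels.

    Parent N carries the BamHI site on both alleles and outer-C (blocking)
    methylation at M on one, so its focal spot runs at half intensity in
    both the [MspI] and [HpaII] patterns.  Parent K lacks the BamHI site on
    both alleles and shows no focal spot.  Panel sizes default to the study
    design: nine reciprocal F1 individuals each, nine selfed progeny of N,
    four of K.
    """
    s_bg, s_nk, s_kn, s_sn, s_sk = _child_seeds(seed, 5)
    specs = (SPOT200_SPEC,) + FILLER_SPECS
    focal = SPOT200_SPEC.name

    def hap(hid: str, b_present: bool, m_state: MethylationState) -> Haplotype:
        return build_genome(
            specs,
            background_length,
            s_bg,
            hap_id=hid,
            variants={focal: LocusVariant(b_present=b_present, m_state=m_state)},
        )

    parent_n = DiploidIndividual(
        "Nipponbare",
        (
            hap("N.a", True, MethylationState.UNMETHYLATED),
            hap("N.b", True, MethylationState.OUTER_C),
        ),
    )
    parent_k = DiploidIndividual(
        "Kasalath",
        (
            hap("K.a", False, MethylationState.UNMETHYLATED),
            hap("K.b", False, MethylationState.UNMETHYLATED),
        ),
    )
    panels = {
        "NKF1": simulate_cross(
            parent_n, parent_k, n_f1, f1_model, s_nk, panel_id="NKF1",
            focal_parent=parent_n.id,
        ),
        "KNF1": simulate_cross(
            parent_k, parent_n, n_f1, f1_model, s_kn, panel_id="KNF1",
            focal_parent=parent_n.id,
        ),
        "N_selfed": simulate_cross(
            parent_n, parent_n, n_selfed_n, selfed_model, s_sn, panel_id="N_selfed"
        ),
        "K_selfed": simulate_cross(
            parent_k, parent_k, n_selfed_k, MENDELIAN, s_sk, panel_id="K_selfed"
        ),
    }
    return Fixture(parent_n, parent_k, panels, SPOT200_SPEC, int(seed))
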
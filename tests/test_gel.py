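"""Fragment enumeration, gel mobility, and spot-pattern synthesis."""

import numpy as np
import pytest

from rlgsim import (
    GelModel,
    Haplotype,
    MethylationState,
    OutOfWindowError,
    diploid_pattern,
    enumerate_fragments,
    haplotype_pattern,
    mobility,
    spot_intensity_at,
)
from rlgsim.enzymes import HPAII, MSPI

from oracle import brute_force_fragments, random_overlay, random_sequence

MS = MethylationState


def plus_fragment(hap, second=MSPI):
    frags = [f for f in enumerate_fragments(hap, second) if f.direction == "+"]
    assert len(frags) == 1
    return frags[0]


class TestEnumerateFragments:
    def test_basic_geometry(self, single_locus_haplotype):
        # NotI cut 7, BamHI cut 21, MspI cut 31.
        frag = plus_fragment(single_locus_haplotype)
        assert (frag.len_1d, frag.end_1d_kind) == (24, "second_enzyme")
        assert (frag.len_2d, frag.end_2d_kind) == (14, "BamHI")
        minus = [f for f in enumerate_fragments(single_locus_haplotype) if f.direction == "-"]
        assert minus[0].end_1d_kind == "sequence_end"

    def test_blocked_site_walks_to_sequence_end(self, single_locus_blocked):
        frag = plus_fragment(single_locus_blocked)
        assert frag.end_1d_kind == "sequence_end"
        assert frag.len_1d == 40 - 7

    def test_hpaii_blocked_by_internal_c_mspi_not(self, single_locus_haplotype):
        hap = Haplotype(
            "h", single_locus_haplotype.sequences, {("c1", 30): MS.INTERNAL_C}
        )
        assert plus_fragment(hap, MSPI).end_1d_kind == "second_enzyme"
        assert plus_fragment(hap, HPAII).end_1d_kind == "sequence_end"

    def test_no_bamhi_runs_on_diagonal(self):
        seq = "A" * 5 + "GCGGCCGC" + "A" * 17 + "CCGG" + "A" * 6
        frag = plus_fragment(Haplotype("h", {"c1": seq}))
        assert frag.len_2d == frag.len_1d == 24
        assert frag.end_2d_kind == "same_as_1d"

    def test_empty_genome_gives_empty_list(self):
        assert enumerate_fragments(Haplotype("h", {})) == []
        assert enumerate_fragments(Haplotype("h", {"c1": ""})) == []

    def test_next_landmark_can_end_the_1d_fragment(self):
        seq = "A" * 5 + "GCGGCCGC" + "A" * 10 + "GCGGCCGC" + "A" * 10
        frags = enumerate_fragments(Haplotype("h", {"c1": seq}))
        inner = [f for f in frags if f.end_1d_kind == "NotI"]
        assert {(f.landmark_cut, f.direction, f.len_1d) for f in inner} == {
            (7, "+", 18),
            (25, "-", 18),
        }


class TestMobility:
    @pytest.mark.parametrize(
        "length,expected", [(100, 1.0), (10_000, 0.0), (1_000, 0.5)]
    )
    def test_log_linear_map(self, length, expected):
        gel = GelModel(window_1d=(100, 10_000), window_2d=(100, 10_000))
        assert mobility(length, 1, gel) == pytest.approx(expected)

    def test_out_of_window_signalled(self, gel):
        with pytest.raises(OutOfWindowError):
            mobility(10, 1, gel)
        with pytest.raises(OutOfWindowError):
            mobility(10**7, 2, gel)

    def test_strictly_decreasing(self, gel):
        lengths = np.linspace(*gel.window_1d, 50)
        xs = [mobility(l, 1, gel) for l in lengths]
        assert all(a > b for a, b in zip(xs, xs[1:]))


def scaled_locus(hap_id="h", chrom="c1", b_present=True, m_state=MS.UNMETHYLATED):
    """Single-locus haplotype with in-window lengths: N cut 700, B 2100, M 3100."""
    seq = (
        "A" * 698
        + "GCGGCCGC"
        + "A" * (2099 - 706)
        + ("GGATCC" if b_present else "GGATCA")
        + "A" * (3099 - 2105)
        + "CCGG"
        + "A" * 400
    )
    overlay = {} if m_state == MS.UNMETHYLATED else {(chrom, 3099): m_state}
    return Haplotype(hap_id, {chrom: seq}, overlay)


class TestPatterns:
    def test_single_locus_haploid_intensity(self, gel):
        pattern = haplotype_pattern(scaled_locus(), "MspI", gel)
        assert [(s.len_1d, s.len_2d, s.intensity) for s in pattern.spots] == [
            (2400, 1400, 0.5)
        ]

    def test_no_landmarks_empty_pattern(self, gel):
        pattern = haplotype_pattern(Haplotype("h", {"c1": "ACGT" * 300}), "MspI", gel)
        assert pattern.spots == []

    def test_comigrating_loci_merge_and_sum(self, gel):
        a = scaled_locus(chrom="c1")
        b = scaled_locus(chrom="c2")
        hap = Haplotype("h", {**a.sequences, **b.sequences})
        pattern = haplotype_pattern(hap, "MspI", gel)
        assert len(pattern.spots) == 1
        spot = pattern.spots[0]
        assert spot.intensity == 1.0
        assert {l[0] for l in spot.loci} == {"c1", "c2"}

    def test_diploid_homozygote_full_heterozygote_half(self, gel):
        homo = diploid_pattern(scaled_locus("a"), scaled_locus("b"), "MspI", gel)
        assert spot_intensity_at(homo, 2400, 1400) == 1.0
        het = diploid_pattern(
            scaled_locus("a"), scaled_locus("b", m_state=MS.OUTER_C), "MspI", gel
        )
        assert spot_intensity_at(het, 2400, 1400) == 0.5

    def test_b_absent_plus_blocked_gives_no_spot(self, gel):
        pattern = diploid_pattern(
            scaled_locus("a", b_present=False),
            scaled_locus("b", m_state=MS.OUTER_C),
            "MspI",
            gel,
        )
        assert spot_intensity_at(pattern, 2400, 1400) == 0.0

    def test_no_overlay_makes_combos_identical(self, gel, fixture_seed1):
        hap = fixture_seed1.parent_k.haplotypes[0]  # unmethylated
        assert hap.overlay == {}
        msp = haplotype_pattern(hap, "MspI", gel)
        hpa = haplotype_pattern(hap, "HpaII", gel)
        assert [(s.len_1d, s.len_2d, s.intensity) for s in msp.spots] == [
            (s.len_1d, s.len_2d, s.intensity) for s in hpa.spots
        ]

    def test_outer_c_never_increases_any_intensity(self, gel):
        base = diploid_pattern(scaled_locus("a"), scaled_locus("b"), "MspI", gel)
        blocked = diploid_pattern(
            scaled_locus("a"), scaled_locus("b", m_state=MS.OUTER_C), "MspI", gel
        )
        for spot in blocked.spots:
            assert spot.intensity <= spot_intensity_at(base, spot.len_1d, spot.len_2d)
        # the affected spot loses exactly one 0.5 quantum
        assert spot_intensity_at(base, 2400, 1400) - spot_intensity_at(
            blocked, 2400, 1400
        ) == 0.5

    def test_total_intensity_of_identical_haplotypes(self, gel):
        hap = scaled_locus("a")
        haploid = haplotype_pattern(hap, "MspI", gel)
        n_frags = round(haploid.total_intensity / 0.5)
        dip = diploid_pattern(hap, scaled_locus("b"), "MspI", gel)
        assert dip.total_intensity == pytest.approx(2 * n_frags * 0.5)


def test_enumeration_matches_brute_force_on_random_genomes():
    """Spot-check against the literal three-step digestion (big run in acceptance)."""
    rng = np.random.default_rng(20_260_926)
    for _ in range(20):
        seq = random_sequence(rng, 3000)
        overlay = random_overlay(rng, seq)
        hap = Haplotype(
            "h", {"c": seq}, {("c", s): MS(v) for s, v in overlay.items()}
        )
        for second in (MSPI, HPAII):
            ours = {
                (f.chrom, f.landmark_cut, f.direction, f.len_1d, f.end_1d_kind,
                 f.len_2d, f.end_2d_kind)
                for f in enumerate_fragments(hap, second)
            }
            assert ours == set(brute_force_fragments(seq, overlay, second.name, "c"))
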
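"""Synthetic genomes, transmission models, and the packaged fixture."""

import math

import pytest

from rlgsim import (
    DEMETHYLATE_PROGENY,
    MAINTAIN_HETEROZYGOUS,
    MENDELIAN,
    IntensityClass,
    LocusSpec,
    MethylationState,
    TransmissionModel,
    build_locus,
    diploid_pattern,
    haplotype_pattern,
    match_spots,
    simulate_cross,
    spot_intensity_at,
)
from rlgsim.pipeline import individual_pattern, panel_classes, present_absent_counts
from rlgsim.simulate import SPOT200_SPEC, LocusVariant, build_genome

from oracle import site_starts

MS = MethylationState
IC = IntensityClass


class TestBuildLocus:
    def test_planted_geometry_produces_declared_lengths(self, gel):
        hap = build_locus(SPOT200_SPEC, 20_000, seed=5)
        pattern = haplotype_pattern(hap, "MspI", gel)
        assert spot_intensity_at(pattern, 2400, 1400) == 0.5

    def test_b_absent_variant_runs_on_diagonal(self, gel):
        hap = build_locus(SPOT200_SPEC, 20_000, seed=5, b_present=False)
        pattern = haplotype_pattern(hap, "MspI", gel)
        assert spot_intensity_at(pattern, 2400, 1400) == 0.0
        assert spot_intensity_at(pattern, 2400, 2400) == 0.5

    def test_overlapping_spacing_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            LocusSpec("bad", "c", 1000, 5, bam_offset=3)

    def test_guard_region_clean_of_accidental_sites(self):
        hap = build_locus(SPOT200_SPEC, 20_000, seed=5)
        seq = hap.sequences["chr11"]
        lo, hi = SPOT200_SPEC.protected_interval
        planted = {w[0] for w in SPOT200_SPEC.site_windows()}
        for rec in ("GCGGCCGC", "CCGG", "GGATCC"):
            hits = {lo + i for i in site_starts(seq[lo:hi], rec)}
            assert hits <= planted

    def test_variants_share_background_byte_for_byte(self):
        a = build_locus(SPOT200_SPEC, 20_000, seed=5)
        b = build_locus(SPOT200_SPEC, 20_000, seed=5, b_present=False,
                        m_state=MS.OUTER_C)
        sa, sb = a.sequences["chr11"], b.sequences["chr11"]
        b_start = SPOT200_SPEC.notI_cut + SPOT200_SPEC.bam_offset - 1
        diff = [i for i, (x, y) in enumerate(zip(sa, sb)) if x != y]
        assert all(b_start <= i < b_start + 6 for i in diff)


class TestSimulateCross:
    def test_negative_panel_size_rejected(self, fixture_seed1):
        with pytest.raises(ValueError):
            simulate_cross(fixture_seed1.parent_n, fixture_seed1.parent_k, -1)

    def test_zero_gives_empty_panel(self, fixture_seed1):
        panel = simulate_cross(fixture_seed1.parent_n, fixture_seed1.parent_k, 0)
        assert panel.individuals == []

    def test_reproducible_from_seed(self, fixture_seed1):
        fx = fixture_seed1
        a = simulate_cross(fx.parent_n, fx.parent_n, 9, MAINTAIN_HETEROZYGOUS, seed=3)
        b = simulate_cross(fx.parent_n, fx.parent_n, 9, MAINTAIN_HETEROZYGOUS, seed=3)
        for ia, ib in zip(a.individuals, b.individuals):
            assert ia.id == ib.id
            for ha, hb in zip(ia.haplotypes, ib.haplotypes):
                assert ha.overlay == hb.overlay
                assert ha.sequences is hb.sequences or ha.sequences == hb.sequences

    def test_maintenance_selfing_keeps_every_progeny_heterozygous(self, fixture_seed1, gel):
        fx = fixture_seed1
        panel = fx.panels["N_selfed"]
        classes = panel_classes(panel, fx.focal_len_1d, fx.focal_len_2d, "MspI", gel)
        assert classes == [IC.HALF] * 9

    def test_partial_maintenance_probability_mixes_models(self, fixture_seed1, gel):
        fx = fixture_seed1
        model = TransmissionModel("maintain_heterozygous", maintenance_prob=0.0)
        panel = simulate_cross(fx.parent_n, fx.parent_n, 40, model, seed=9)
        classes = panel_classes(panel, fx.focal_len_1d, fx.focal_len_2d, "MspI", gel)
        # with zero maintenance the panel segregates: not everyone stays half
        assert set(classes) > {IC.HALF}

    def test_demethylation_model_restores_full_intensity(self, fixture_seed1, gel):
        fx = fixture_seed1
        panel = simulate_cross(fx.parent_n, fx.parent_n, 6, DEMETHYLATE_PROGENY, seed=4)
        classes = panel_classes(panel, fx.focal_len_1d, fx.focal_len_2d, "MspI", gel)
        assert classes == [IC.FULL] * 6

    def test_mendelian_f1_segregates_one_to_one(self, fixture_seed1, gel):
        fx = fixture_seed1
        panel = simulate_cross(fx.parent_n, fx.parent_k, 500, MENDELIAN, seed=12)
        present, absent = present_absent_counts(
            panel_classes(panel, fx.focal_len_1d, fx.focal_len_2d, "MspI", gel)
        )
        assert present + absent == 500
        se = math.sqrt(0.25 / 500)
        assert abs(present / 500 - 0.5) <= 3 * se


class TestFixture:
    def test_parent_n_focal_spot_half_in_both_combos(self, fixture_seed1, gel):
        fx = fixture_seed1
        for combo in ("MspI", "HpaII"):
            pattern = diploid_pattern(*fx.parent_n.haplotypes, combo, gel)
            assert spot_intensity_at(pattern, 2400, 1400) == 0.5

    def test_parent_k_focal_spot_absent(self, fixture_seed1, gel):
        pattern = diploid_pattern(*fixture_seed1.parent_k.haplotypes, "MspI", gel)
        assert spot_intensity_at(pattern, 2400, 1400) == 0.0

    def test_f1_spot_presence_tracks_transmitted_epiallele(self, fixture_seed1, gel):
        fx = fixture_seed1
        m_site = ("chr11", SPOT200_SPEC.m_start)
        for ind in fx.panels["NKF1"].individuals:
            n_hap = next(
                h for h in ind.haplotypes if h.meta["source_parent"] == "Nipponbare"
            )
            expected = 0.0 if m_site in n_hap.overlay else 0.5
            pattern = individual_pattern(ind, "MspI", gel)
            assert spot_intensity_at(pattern, 2400, 1400) == expected

    def test_only_focal_locus_spots_differ_between_parents(self, fixture_seed1, gel):
        """Background screening: every differing spot traces to the focal locus."""
        fx = fixture_seed1
        pn = diploid_pattern(*fx.parent_n.haplotypes, "MspI", gel)
        pk = diploid_pattern(*fx.parent_k.haplotypes, "MspI", gel)
        focal_cuts = {
            SPOT200_SPEC.notI_cut,
            SPOT200_SPEC.notI_cut + SPOT200_SPEC.next_notI_offset,
        }
        for m in match_spots(pn, pk):
            if m.status == "both" and m.intensity_ratio == 1.0:
                continue
            spot = m.a if m.a is not None else m.b
            assert {l[1] for l in spot.loci} <= focal_cuts

    def test_multi_locus_composition(self, gel):
        specs = [
            LocusSpec("L1", "c1", 8_000, 2400, bam_offset=1400),
            LocusSpec("L2", "c2", 8_000, 3000, bam_offset=1800),
        ]
        hap = build_genome(
            specs, 15_000, seed=3,
            variants={"L2": LocusVariant(m_state=MS.INTERNAL_C)},
        )
        msp = haplotype_pattern(hap, "MspI", gel)
        hpa = haplotype_pattern(hap, "HpaII", gel)
        assert spot_intensity_at(msp, 3000, 1800) == 0.5
        assert spot_intensity_at(hpa, 3000, 1800) == 0.0
        assert spot_intensity_at(hpa, 2400, 1400) == 0.5
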
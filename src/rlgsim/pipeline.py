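"""Stage glue: digest -> classify -> segregate, for panels and fixtures.

These helpers run the virtual RLGS stages end to end on simulated
individuals and panels.  Each individual's spot intensities are classified
against the modal intensity of its own pattern (the "surrounding spots"
baseline), so classification never peeks at the simulated genotype.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple, Union

from .compare import (
    IntensityClass,
    classify_intensity,
    modal_intensity,
    spot_intensity_at,
)
from .gel import Enzyme, GelModel, SpotPattern, diploid_pattern
from .segregation import LocusObservation, SegregationResult, flag_non_mendelian
from .simulate import CrossPanel, DiploidIndividual, Fixture


def individual_pattern(
    ind: DiploidIndividual,
    combo: Union[str, Enzyme],
    gel: GelModel = GelModel(),
    **opts,
) -> SpotPattern:
    """Diploid spot pattern of one simulated individual."""
    a, b = ind.haplotypes
    return diploid_pattern(a, b, combo, gel, sample_id=ind.id, **opts)


def classify_spot(
    pattern: SpotPattern,
    len_1d: float,
    len_2d: float,
    match_tol: float = 0.01,
    ratio_tol: float = 0.1,
    baseline: Optional[float] = None,
) -> IntensityClass:
    """Intensity class of the spot at (len_1d, len_2d) in one pattern.

    The baseline defaults to the pattern's modal spot intensity.
    """
    if baseline is None:
        baseline = modal_intensity(pattern)
    intensity = spot_intensity_at(pattern, len_1d, len_2d, match_tol)
    return classify_intensity(intensity, baseline, ratio_tol)


def panel_classes(
    panel: CrossPanel,
    len_1d: float,
    len_2d: float,
    combo: Union[str, Enzyme],
    gel: GelModel = GelModel(),
    match_tol: float = 0.01,
    ratio_tol: float = 0.1,
) -> List[IntensityClass]:
    """Classify the focal spot in every individual of a panel."""
    return [
        classify_spot(
            individual_pattern(ind, combo, gel), len_1d, len_2d, match_tol, ratio_tol
        )
        for ind in panel.individuals
    ]


def panel_observation(
    panel: CrossPanel,
    locus: str,
    len_1d: float,
    len_2d: float,
    parent_genotype: Tuple[bool, bool],
    combo: Union[str, Enzyme],
    cross_type: str = "self",
    parent_b_genotype: Optional[Tuple[bool, bool]] = None,
    gel: GelModel = GelModel(),
    generation: str = "selfed",
    **opts,
) -> LocusObservation:
    """Classified panel bundled with its Mendelian expectation inputs."""
    combo_name = combo if isinstance(combo, str) else combo.name
    return LocusObservation(
        locus=locus,
        combo=combo_name,
        classes=panel_classes(panel, len_1d, len_2d, combo, gel, **opts),
        parent_genotype=parent_genotype,
        generation=generation,
        cross_type=cross_type,
        parent_b_genotype=parent_b_genotype,
    )


def fixture_segregation(
    fixture: Fixture,
    combos: Sequence[str] = ("MspI", "HpaII"),
    gel: GelModel = GelModel(),
    alpha: float = 0.05,
    correction: str = "bh",
) -> Dict[str, List[SegregationResult]]:
    """Segregation analysis of every fixture panel, per enzyme combination."""
    locus = f"{fixture.focal_spec.chrom}:{fixture.focal_spec.notI_cut}:+"
    out: Dict[str, List[SegregationResult]] = {}
    for panel_name, panel in fixture.panels.items():
        selfed = panel.mother_id == panel.father_id
        observations = [
            panel_observation(
                panel,
                locus,
                fixture.focal_len_1d,
                fixture.focal_len_2d,
                parent_genotype=(
                    fixture.parent_n_genotype
                    if panel.mother_id == fixture.parent_n.id or not selfed
                    else fixture.parent_k_genotype
                ),
                combo=combo,
                cross_type="self" if selfed else "outcross_F1",
                parent_b_genotype=None if selfed else fixture.parent_k_genotype,
                gel=gel,
                generation="selfed" if selfed else "F1",
            )
            for combo in combos
        ]
        out[panel_name] = flag_non_mendelian(observations, alpha=alpha, correction=correction)
    return out


def present_absent_counts(classes: Sequence[IntensityClass]) -> Tuple[int, int]:
    """Spot-present (half or full) vs spot-absent counts of a panel."""
    present = sum(1 for c in classes if c in (IntensityClass.HALF, IntensityClass.FULL))
    absent = sum(1 for c in classes if c == IntensityClass.ABSENT)
    return present, absent


def plot_pattern(pattern: SpotPattern, path) -> None:
    """Optional spot-scatter rendering (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [s.x1 for s in pattern.spots]
    ys = [s.x2 for s in pattern.spots]
    sizes = [80 * s.intensity for s in pattern.spots]
    ax.scatter(xs, ys, s=sizes, c="black")
    ax.set_xlabel("1D mobility")
    ax.set_ylabel("2D mobility")
    ax.set_title(f"{pattern.sample_id} [{pattern.combo}]")
    ax.set_xlim(0, 1)
    ax.set_ylim(1, 0)
    fig.savefig(path, dpi=150)
    plt.close(fig)
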
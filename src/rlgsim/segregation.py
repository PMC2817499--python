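"""Per-locus segregation testing and non-Mendelian inheritance flagging.

Spot intensity classes map directly to allele dosage at a locus: ``full``
(both alleles produce the fragment), ``half`` (one allele), ``absent``
(neither).  Under Mendelian transmission, each parent passes one of its two
(allele, epiallele) pairs with probability 1/2, so a heterozygous producer
crossed to a non-producer gives a 1:1 half:absent F1 ratio, and selfing a
heterozygote gives 1:2:1 full:half:absent.  A selfed panel in which every
individual stays half-intensity (the parent's heterozygous methylation
configuration re-established in all progeny) is the canonical non-Mendelian
signature.

Tests are exact: a two-sided exact binomial for two classes (two-sidedness
by summing all outcomes no more probable than the observed one) and an
exact multinomial, fully enumerated for n <= 20 and Monte-Carlo estimated
with a fixed seed beyond that.  Multiple loci within one run are corrected
by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .compare import IntensityClass

# Same relative slack scipy's binomtest uses when comparing outcome
# probabilities, so the two-class multinomial path agrees with it exactly.
_PMF_SLACK = 1 + 1e-7


def mendelian_expectation(
    parent_a: Tuple[bool, bool],
    parent_b: Optional[Tuple[bool, bool]],
    cross_type: str,
) -> Dict[IntensityClass, float]:
    """Expected intensity-class probabilities under Mendelian transmission.

    Parents are given as per-allele spot-production flags.  ``outcross_F1``
    combines one gamete from each parent; ``self`` requires a single parent
    (``parent_b`` omitted or identical).  Classes with zero probability are
    dropped.
    """
    if cross_type == "self":
        if parent_b is not None and tuple(parent_b) != tuple(parent_a):
            raise ValueError("selfing requires a single parent genotype")
        parent_b = parent_a
    elif cross_type != "outcross_F1":
        raise ValueError(f"unknown cross type {cross_type!r}")
    if parent_b is None:
        raise ValueError("outcross_F1 requires both parents")
    pa = sum(bool(x) for x in parent_a) / 2.0
    pb = sum(bool(x) for x in parent_b) / 2.0
    probs = {
        IntensityClass.FULL: pa * pb,
        IntensityClass.HALF: pa * (1 - pb) + (1 - pa) * pb,
        IntensityClass.ABSENT: (1 - pa) * (1 - pb),
    }
    return {k: v for k, v in probs.items() if v > 0}


def _aligned(observed: Mapping, expected: Mapping) -> Tuple[List[int], List[float]]:
    classes = sorted(set(observed) | set(expected), key=str)
    counts = [int(observed.get(c, 0)) for c in classes]
    probs = [float(expected.get(c, 0.0)) for c in classes]
    if any(c < 0 for c in counts):
        raise ValueError("negative class count")
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError(f"expected probabilities sum to {sum(probs)}, not 1")
    return counts, probs


def segregation_test(
    observed: Mapping,
    expected: Mapping,
    seed: int = 0,
    mc_draws: int = 100_000,
) -> float:
    """Exact goodness-of-fit p-value of observed class counts.

    Two effective classes use the two-sided exact binomial; three or more
    use the exact multinomial (all outcomes with probability no larger than
    the observed one), enumerated exhaustively for n <= 20 and otherwise
    Monte-Carlo estimated with the given seed.  An observation in a
    zero-probability class gives p = 0.
    """
    counts, probs = _aligned(observed, expected)
    n = sum(counts)
    if n < 1:
        raise ValueError("segregation test needs at least one classified individual")
    # Outcomes in impossible classes falsify the expectation outright.
    if any(c > 0 and p == 0.0 for c, p in zip(counts, probs)):
        return 0.0
    keep = [i for i, p in enumerate(probs) if p > 0]
    counts = [counts[i] for i in keep]
    probs = [probs[i] for i in keep]
    if len(counts) == 1:
        return 1.0
    if len(counts) == 2:
        return float(stats.binomtest(counts[0], n, probs[0]).pvalue)
    return _exact_multinomial(counts, probs, n, seed, mc_draws)


def _exact_multinomial(
    counts: Sequence[int], probs: Sequence[float], n: int, seed: int, mc_draws: int
) -> float:
    dist = stats.multinomial(n, probs)
    p_obs = float(dist.pmf(counts))
    if n <= 20:
        outcomes = np.array(list(_compositions(n, len(counts))))
        pmfs = dist.pmf(outcomes)
        return float(pmfs[pmfs <= p_obs * _PMF_SLACK].sum())
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=mc_draws)
    pmfs = dist.pmf(draws)
    hits = int((pmfs <= p_obs * _PMF_SLACK).sum())
    return (hits + 1) / (mc_draws + 1)


def _compositions(n: int, k: int):
    """All k-tuples of non-negative ints summing to n (stars and bars)."""
    for bars in _combinations(range(n + k - 1), k - 1):
        prev = -1
        out = []
        for b in bars:
            out.append(b - prev - 1)
            prev = b
        out.append(n + k - 2 - prev)
        yield tuple(out)


@dataclass
class LocusObservation:
    """Classified progeny panel for one locus under one enzyme combination."""

    locus: str
    combo: str
    classes: Sequence[IntensityClass]
    parent_genotype: Tuple[bool, bool]
    generation: str = "selfed"
    cross_type: str = "self"
    parent_b_genotype: Optional[Tuple[bool, bool]] = None


@dataclass
class SegregationResult:
    locus: str
    combo: str
    observed: Dict[IntensityClass, int]
    expected: Dict[IntensityClass, float]
    test: str
    p_value: float
    p_adjusted: float
    verdict: str  # 'mendelian_consistent' | 'non_mendelian_flag'
    n_other: int = 0
    generation: str = "selfed"


def flag_non_mendelian(
    observations: Sequence[LocusObservation],
    alpha: float = 0.05,
    correction: str = "bh",
    seed: int = 0,
) -> List[SegregationResult]:
    """Test each locus against its Mendelian expectation and flag deviants.

    Individuals classified ``other`` are excluded from the test and counted
    in ``n_other``.  BH-adjusted p-values below ``alpha`` flag the locus
    ``non_mendelian_flag``; pass ``correction="none"`` to skip adjustment.
    """
    if correction not in ("bh", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    results: List[SegregationResult] = []
    for obs in observations:
        usable = [c for c in obs.classes if c != IntensityClass.OTHER]
        n_other = len(obs.classes) - len(usable)
        counts: Dict[IntensityClass, int] = {}
        for c in usable:
            counts[c] = counts.get(c, 0) + 1
        expected = mendelian_expectation(
            obs.parent_genotype, obs.parent_b_genotype, obs.cross_type
        )
        p = segregation_test(counts, expected, seed=seed)
        effective = sum(1 for v in expected.values() if v > 0)
        test_name = "exact_binomial" if effective <= 2 else "exact_multinomial"
        results.append(
            SegregationResult(
                locus=obs.locus,
                combo=obs.combo,
                observed=counts,
                expected=expected,
                test=test_name,
                p_value=p,
                p_adjusted=p,
                verdict="",
                n_other=n_other,
                generation=obs.generation,
            )
        )
    if results:
        ps = np.array([r.p_value for r in results])
        adj = stats.false_discovery_control(ps, method="bh") if correction == "bh" else ps
        for r, pa in zip(results, adj):
            r.p_adjusted = float(min(pa, 1.0))
            r.verdict = (
                "non_mendelian_flag" if r.p_adjusted < alpha else "mendelian_consistent"
            )
    return results
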
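"""GS''N vs S'PA enrichment at serine-meaningful positions.

Two disjoint substitution groups partition the serine neighbourhood:

* ``GS2N`` — glycine, asparagine, and serine encoded AGY (transition
  neighbours of the AGY codon set); enriched at diversifying positions.
* ``S1PA`` — proline, alanine, and serine encoded TCN (first-position
  mutation neighbours of the TCN set); enriched at conserved positions.

Per position the *fraction* of sequences falling in each group is the sample
unit for all rank statistics: Spearman correlation of fraction with
diversity, Mann-Whitney contrasts between diversity-quartile extremes
(genome-style, two-tailed) and between hotspot and other positions
(gp120-style, one-tailed).  Analysis is always restricted to positions where
serine is a meaningful amino acid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, spearmanr

from .diversity import PositionProfile, diversity_quartiles, profiles_from_alignment
from .genetic_code import SERINE_AGY, SERINE_TCN, STOP_CODONS, CODON_TO_AA
from .split_blosum import AlignmentBlock


@dataclass(frozen=True)
class SubstitutionGroup:
    """Membership predicate over (amino acid, codon).

    Serine codons are classified by their codon set; every other amino acid
    by identity.  The default member sets follow the GS2N / S1PA definitions;
    they are configurable because one Methods passage prints the second group
    as "S'PT" — the package treats that as a typo for S'PA but lets the user
    test either reading.
    """

    name: str
    amino_acids: frozenset[str]
    serine_codons: frozenset[str]

    def contains(self, codon: str) -> bool:
        codon = codon.upper()
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            return False
        if aa == "S":
            return codon in self.serine_codons
        return aa in self.amino_acids


GS2N = SubstitutionGroup("GS2N", frozenset("GN"), SERINE_AGY)
S1PA = SubstitutionGroup("S1PA", frozenset("PA"), SERINE_TCN)


def group_fraction(column, group: SubstitutionGroup) -> float:
    """Fraction of non-gap codons in an alignment column matching ``group``."""
    codons = [c.upper() for c in column
              if "-" not in c and c.upper() not in STOP_CODONS]
    if not codons:
        raise ValueError("column is empty after gap/stop removal")
    return sum(group.contains(c) for c in codons) / len(codons)


def fraction_from_profile(profile: PositionProfile, group: SubstitutionGroup) -> float:
    """Group fraction from a profile's split-symbol counts (codon mode)."""
    counts = profile.split_counts
    hit = 0
    for sym, count in counts.items():
        if sym == "S1":
            hit += count if "TCT" in group.serine_codons else 0
        elif sym == "S2":
            hit += count if "AGT" in group.serine_codons else 0
        elif sym in group.amino_acids:
            hit += count
    return hit / profile.depth


def correlate_with_diversity(fractions, diversities):
    """Spearman rank correlation (rho, two-sided p) of fraction vs diversity."""
    fractions = np.asarray(fractions, dtype=float)
    diversities = np.asarray(diversities, dtype=float)
    if fractions.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(fractions == fractions[0]) or np.all(diversities == diversities[0]):
        raise ValueError("correlation undefined for constant input")
    rho, p = spearmanr(fractions, diversities)
    return float(rho), float(p)


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    medians: dict[str, float] = field(default_factory=dict)


def quartile_test(fractions_high, fractions_low, tail: str = "two") -> RankTestResult:
    """Mann-Whitney U between high- and low-diversity position fractions.

    ``tail`` is ``"two"`` (genome-style) or ``"one"`` — one-sided, testing
    high > low.
    """
    high = np.asarray(fractions_high, dtype=float)
    low = np.asarray(fractions_low, dtype=float)
    if high.size == 0 or low.size == 0:
        raise ValueError("both quartile groups must be non-empty")
    alternative = {"two": "two-sided", "one": "greater"}[tail]
    u, p = mannwhitneyu(high, low, alternative=alternative)
    return RankTestResult(float(u), float(p),
                          {"high": float(np.median(high)), "low": float(np.median(low))})


def hotspot_test(fractions: dict[int, float], labels: dict[int, str],
                 group_name: str = "GS2N") -> RankTestResult:
    """One-tailed Mann-Whitney of hotspot vs other position fractions.

    GS2N is tested hotspot > other; S1PA is tested hotspot < other, matching
    the directional hypotheses for diversifying vs conserved regions.
    ``fractions`` and ``labels`` are keyed by position.
    """
    hot = [f for pos, f in fractions.items() if labels.get(pos) == "hotspot"]
    other = [f for pos, f in fractions.items() if labels.get(pos) == "other"]
    if not hot or not other:
        raise ValueError("both regions must contain analyzed positions")
    alternative = "greater" if group_name == "GS2N" else "less"
    u, p = mannwhitneyu(hot, other, alternative=alternative)
    return RankTestResult(float(u), float(p),
                          {"hotspot": float(np.median(hot)),
                           "other": float(np.median(other))})


@dataclass
class EnrichmentResult:
    """Full genome-style analysis of one codon alignment."""

    profiles: list[PositionProfile]
    serine_positions: list[int]          # indices into ``profiles``
    fractions: dict[str, dict[int, float]]   # group -> profile index -> fraction
    spearman: dict[str, tuple[float, float]]
    quartile: dict[str, RankTestResult]


def analyze_alignment(block: AlignmentBlock,
                      groups: tuple[SubstitutionGroup, ...] = (GS2N, S1PA),
                      tail: str = "two") -> EnrichmentResult:
    """Run the diversity-vs-substitution-group analysis on one alignment.

    Profiles every codon column, restricts to serine-meaningful positions,
    computes per-position group fractions, then the Spearman correlation with
    diversity and the top-vs-bottom diversity-quartile Mann-Whitney test for
    each group.
    """
    profiles = profiles_from_alignment(block)
    serine_idx = [i for i, pr in enumerate(profiles) if pr.serine_meaningful]
    fractions = {
        g.name: {i: fraction_from_profile(profiles[i], g) for i in serine_idx}
        for g in groups
    }
    diversities = {i: profiles[i].diversity for i in serine_idx}
    spearman = {}
    quartile = {}
    if len(serine_idx) >= 4:
        part = diversity_quartiles([diversities[i] for i in serine_idx])
        high = [serine_idx[j] for j in part.high]
        low = [serine_idx[j] for j in part.low]
        for g in groups:
            fr = fractions[g.name]
            try:
                spearman[g.name] = correlate_with_diversity(
                    [fr[i] for i in serine_idx], [diversities[i] for i in serine_idx])
            except ValueError:
                spearman[g.name] = (float("nan"), float("nan"))
            if high and low:
                quartile[g.name] = quartile_test(
                    [fr[i] for i in high], [fr[i] for i in low], tail=tail)
    return EnrichmentResult(profiles, serine_idx, fractions, spearman, quartile)


def analyze_regions(block: AlignmentBlock, labels: dict[int, str],
                    groups: tuple[SubstitutionGroup, ...] = (GS2N, S1PA),
                    ) -> dict[str, RankTestResult]:
    """gp120-style hotspot-vs-rest one-tailed tests on one alignment.

    ``labels`` maps 0-based codon-column indices to ``"hotspot"`` or
    ``"other"``; positions are restricted to serine-meaningful ones first.
    """
    profiles = profiles_from_alignment(block)
    serine_idx = [i for i, pr in enumerate(profiles) if pr.serine_meaningful]
    results = {}
    for g in groups:
        fractions = {profiles[i].position: fraction_from_profile(profiles[i], g)
                     for i in serine_idx}
        pos_labels = {profiles[i].position: labels.get(profiles[i].position, "other")
                      for i in serine_idx}
        results[g.name] = hotspot_test(fractions, pos_labels, group_name=g.name)
    return results
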
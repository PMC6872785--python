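"""B-cell-receptor heavy-chain repertoire analysis of serine codon usage.

Input records are pre-aligned, IMGT-numbered V-region nucleotide sequences
paired position-for-position with their germline.  The pipeline:

1. filter: drop sequences with > 30% mutated nucleotides and individuals
   left with fewer than 3 sequences;
2. clone grouping: same V gene, J gene and CDR3 length; within a clone each
   distinct mutational event (position, germline codon, observed codon) is
   counted once regardless of how many members carry it;
3. positions: analysis is restricted to the IMGT positions 25-30, 35-59,
   63-72, 74-106 and to positions covered by at least 30 sequences;
4. per individual, serine-meaningful positions are called from the germline
   amino-acid profile across clones, then CDR-vs-FWR contrasts are formed
   for germline group usage (clone fractions) and somatic substitutions
   (GS2N share of GS2N + S1PA);
5. across individuals, a Wilcoxon signed-rank test on the per-individual
   CDR minus FWR differences.

IMGT region bounds (1-based inclusive): FWR1 1-24, CDR1 25-40, FWR2 41-53,
CDR2 56-65, FWR3 66-104, CDR3 from 105 (analysis stops at 106).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon

from .diversity import PositionProfile
from .enrichment import GS2N, S1PA, SubstitutionGroup
from .genetic_code import CODON_TO_AA

MAX_MUTATION_FRACTION = 0.30
MIN_POSITION_COVERAGE = 30
LAST_ANALYZED_POSITION = 106

_GAP_CHARS = set("-.")


@dataclass
class ReceptorRecord:
    """One heavy-chain read aligned to its germline (IMGT numbering)."""

    individual: str
    sequence: str
    germline: str
    v_call: str
    j_call: str
    cdr3_length: int
    imgt_start: int = 1   # 1-based IMGT amino-acid position of the first codon

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.germline):
            raise ValueError(
                f"sequence/germline length mismatch for {self.individual}: "
                f"{len(self.sequence)} vs {len(self.germline)}")
        self.sequence = self.sequence.upper()
        self.germline = self.germline.upper()

    def _codon_at(self, source: str, position: int) -> str | None:
        offset = 3 * (position - self.imgt_start)
        if offset < 0 or offset + 3 > len(source):
            return None
        codon = source[offset:offset + 3]
        if any(ch in _GAP_CHARS for ch in codon):
            return None
        return codon

    def codon(self, position: int) -> str | None:
        """Gap-free observed codon at a 1-based IMGT position, else None."""
        return self._codon_at(self.sequence, position)

    def germline_codon(self, position: int) -> str | None:
        return self._codon_at(self.germline, position)

    def mutated_fraction(self) -> float:
        """Mismatch fraction over positions where both strands have a base."""
        pairs = [(a, b) for a, b in zip(self.sequence, self.germline)
                 if a not in _GAP_CHARS and b not in _GAP_CHARS]
        if not pairs:
            raise ValueError("record has no aligned nucleotides")
        return sum(a != b for a, b in pairs) / len(pairs)

    @property
    def clone_key(self) -> tuple[str, str, int]:
        return (self.v_call, self.j_call, self.cdr3_length)


@dataclass(frozen=True)
class RegionMask:
    """IMGT CDR/FWR interval definitions, 1-based inclusive."""

    fwr1: tuple[int, int] = (1, 24)
    cdr1: tuple[int, int] = (25, 40)
    fwr2: tuple[int, int] = (41, 53)
    cdr2: tuple[int, int] = (56, 65)
    fwr3: tuple[int, int] = (66, 104)
    cdr3: tuple[int, int] = (105, LAST_ANALYZED_POSITION)
    analyzed: frozenset[int] = frozenset(
        set(range(25, 31)) | set(range(35, 60)) | set(range(63, 73))
        | set(range(74, LAST_ANALYZED_POSITION + 1)))

    def region_of(self, position: int) -> str | None:
        for name, (lo, hi) in (("FWR", self.fwr1), ("CDR", self.cdr1),
                               ("FWR", self.fwr2), ("CDR", self.cdr2),
                               ("FWR", self.fwr3), ("CDR", self.cdr3)):
            if lo <= position <= hi:
                return name
        return None


@dataclass
class FilterReport:
    dropped_mutation: int = 0
    dropped_individuals: list[str] = field(default_factory=list)
    dropped_few_sequences: int = 0


def filter_records(
    records: list[ReceptorRecord],
    max_mutation_fraction: float = MAX_MUTATION_FRACTION,
    min_sequences: int = 3,
) -> tuple[list[ReceptorRecord], FilterReport]:
    """Apply the sequence- and individual-level filters.

    Sequences with a mutated-nucleotide fraction strictly above the threshold
    are removed first; individuals left with fewer than ``min_sequences``
    sequences are then removed entirely.
    """
    report = FilterReport()
    kept = []
    for rec in records:
        if rec.mutated_fraction() > max_mutation_fraction:
            report.dropped_mutation += 1
        else:
            kept.append(rec)
    per_individual = Counter(r.individual for r in kept)
    for ind, n in sorted(per_individual.items()):
        if n < min_sequences:
            report.dropped_individuals.append(ind)
    dropped = set(report.dropped_individuals)
    final = [r for r in kept if r.individual not in dropped]
    report.dropped_few_sequences = len(kept) - len(final)
    return final, report


@dataclass
class Clone:
    """Records sharing (V gene, J gene, CDR3 length) within one individual."""

    individual: str
    key: tuple[str, str, int]
    members: list[ReceptorRecord]

    def germline_codon(self, position: int) -> str | None:
        for rec in self.members:
            codon = rec.germline_codon(position)
            if codon is not None:
                return codon
        return None

    def events(self, positions) -> set[tuple[int, str, str]]:
        """Distinct mutational events (position, germline codon, observed).

        Each event is counted once per clone no matter how many members carry
        it; both codons must be gap-free and differ.
        """
        out: set[tuple[int, str, str]] = set()
        for rec in self.members:
            for pos in positions:
                germ, obs = rec.germline_codon(pos), rec.codon(pos)
                if germ is not None and obs is not None and germ != obs:
                    out.add((pos, germ, obs))
        return out


def group_clones(records: list[ReceptorRecord]) -> list[Clone]:
    """Partition records into clones by individual and (V, J, CDR3 length)."""
    groups: dict[tuple, list[ReceptorRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.individual, rec.clone_key)].append(rec)
    return [Clone(ind, key, members)
            for (ind, key), members in sorted(groups.items())]


def position_coverage_filter(
    records: list[ReceptorRecord],
    mask: RegionMask = RegionMask(),
    min_sequences: int = MIN_POSITION_COVERAGE,
) -> frozenset[int]:
    """Analyzed positions covered by at least ``min_sequences`` sequences."""
    coverage = Counter()
    for rec in records:
        for pos in mask.analyzed:
            if rec.codon(pos) is not None:
                coverage[pos] += 1
    return frozenset(p for p in mask.analyzed if coverage[p] >= min_sequences)


def germline_profiles(clones: list[Clone], positions) -> dict[int, PositionProfile]:
    """Per-position germline amino-acid profile across clones (clone = unit)."""
    profiles: dict[int, PositionProfile] = {}
    for pos in sorted(positions):
        profile = PositionProfile(pos - 1)
        for clone in clones:
            codon = clone.germline_codon(pos)
            if codon is None or codon not in CODON_TO_AA:
                continue
            aa = CODON_TO_AA[codon]
            profile.aa_counts[aa] += 1
            if aa == "S":
                profile.split_counts["S2" if codon.startswith("AG") else "S1"] += 1
            else:
                profile.split_counts[aa] += 1
        if profile.depth > 0:
            profiles[pos] = profile
    return profiles


def serine_meaningful_positions(clones: list[Clone], positions) -> frozenset[int]:
    """Positions where serine is meaningful in the germline profile."""
    profiles = germline_profiles(clones, positions)
    return frozenset(p for p, pr in profiles.items() if pr.serine_meaningful)


@dataclass
class IndividualSummary:
    """Per-individual CDR-vs-FWR contrasts of the two substitution groups."""

    individual: str
    germline_medians: dict[str, dict[str, float]] = field(default_factory=dict)
    germline_difference: dict[str, float] = field(default_factory=dict)
    somatic_medians: dict[str, float] = field(default_factory=dict)
    somatic_difference: float | None = None


def _region_medians(values: dict[int, float], mask: RegionMask) -> dict[str, float]:
    by_region = defaultdict(list)
    for pos, v in values.items():
        region = mask.region_of(pos)
        if region is not None:
            by_region[region].append(v)
    return {region: float(np.median(vals)) for region, vals in by_region.items()}


def germline_region_contrast(
    clones: list[Clone],
    positions,
    mask: RegionMask = RegionMask(),
    groups: tuple[SubstitutionGroup, ...] = (GS2N, S1PA),
) -> IndividualSummary:
    """Germline group usage per region for one individual's clones.

    At each serine-meaningful position the fraction of clones whose germline
    codon satisfies the group predicate is computed; the summary holds the
    median of those fractions over CDR and over FWR positions and their
    difference (CDR minus FWR) per group.
    """
    if not clones:
        raise ValueError("no clones for this individual")
    individual = clones[0].individual
    meaningful = serine_meaningful_positions(clones, positions)
    summary = IndividualSummary(individual)
    for group in groups:
        fractions: dict[int, float] = {}
        for pos in meaningful:
            codons = [c for c in (cl.germline_codon(pos) for cl in clones)
                      if c is not None]
            if codons:
                fractions[pos] = sum(group.contains(c) for c in codons) / len(codons)
        medians = _region_medians(fractions, mask)
        summary.germline_medians[group.name] = medians
        if "CDR" in medians and "FWR" in medians:
            summary.germline_difference[group.name] = medians["CDR"] - medians["FWR"]
    return summary


def somatic_region_contrast(
    clones: list[Clone],
    positions,
    mask: RegionMask = RegionMask(),
    groups: tuple[SubstitutionGroup, ...] = (GS2N, S1PA),
) -> IndividualSummary | None:
    """Somatic GS2N share (of GS2N + S1PA) per region for one individual.

    Positions restricted to serine-meaningful ones carrying at least one
    mutational event; per position the deduplicated substituted codons are
    classified and the GS2N / (GS2N + S1PA) share taken.  Returns None when
    the individual has no usable substitutions (excluded from the cohort
    statistic, as for an individual with no events at analyzed positions).
    """
    if not clones:
        raise ValueError("no clones for this individual")
    meaningful = serine_meaningful_positions(clones, positions)
    group_a, group_b = groups
    shares: dict[int, float] = {}
    for pos in meaningful:
        observed = [obs for clone in clones
                    for (_, _, obs) in clone.events([pos])]
        if not observed:
            continue
        a = sum(group_a.contains(c) for c in observed)
        b = sum(group_b.contains(c) for c in observed)
        if a + b > 0:
            shares[pos] = a / (a + b)
    medians = _region_medians(shares, mask)
    if "CDR" not in medians or "FWR" not in medians:
        return None
    summary = IndividualSummary(clones[0].individual)
    summary.somatic_medians = medians
    summary.somatic_difference = medians["CDR"] - medians["FWR"]
    return summary


@dataclass
class CohortTest:
    successes: int
    total: int
    p_value: float


def cross_individual_test(differences) -> CohortTest:
    """Wilcoxon signed-rank test on per-individual CDR minus FWR differences.

    A success is a strictly positive difference.  The p-value is the exact
    two-sided signed-rank probability where scipy's exact mode applies.
    """
    diffs = np.asarray(list(differences), dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least 2 individuals")
    if np.all(diffs == 0):
        raise ValueError("all differences are zero; signed-rank test degenerate")
    # exact signed-rank null for small cohorts (ties would otherwise force
    # the normal approximation)
    method = "exact" if diffs.size <= 25 else "auto"
    stat, p = wilcoxon(diffs, method=method)
    return CohortTest(int(np.sum(diffs > 0)), int(diffs.size), float(p))


@dataclass
class RepertoireResult:
    filter_report: FilterReport
    analyzed_positions: frozenset[int]
    summaries: list[IndividualSummary]
    somatic_summaries: list[IndividualSummary]
    germline_tests: dict[str, CohortTest]
    somatic_test: CohortTest | None


def run_repertoire_analysis(
    records: list[ReceptorRecord],
    mask: RegionMask = RegionMask(),
    min_coverage: int = MIN_POSITION_COVERAGE,
    max_mutation_fraction: float = MAX_MUTATION_FRACTION,
) -> RepertoireResult:
    """The full pipeline: filters, clones, contrasts, cohort tests."""
    kept, report = filter_records(records, max_mutation_fraction)
    if not kept:
        raise ValueError("no records left after filtering")
    positions = position_coverage_filter(kept, mask, min_coverage)
    clones = group_clones(kept)
    by_individual: dict[str, list[Clone]] = defaultdict(list)
    for clone in clones:
        by_individual[clone.individual].append(clone)

    summaries, somatic_summaries = [], []
    for ind in sorted(by_individual):
        summaries.append(germline_region_contrast(by_individual[ind], positions, mask))
        somatic = somatic_region_contrast(by_individual[ind], positions, mask)
        if somatic is not None:
            somatic_summaries.append(somatic)

    germline_tests = {}
    for group in (GS2N, S1PA):
        diffs = [s.germline_difference[group.name] for s in summaries
                 if group.name in s.germline_difference]
        if len(diffs) >= 2 and any(d != 0 for d in diffs):
            germline_tests[group.name] = cross_individual_test(diffs)
    somatic_test = None
    somatic_diffs = [s.somatic_difference for s in somatic_summaries
                     if s.somatic_difference is not None]
    if len(somatic_diffs) >= 2 and any(d != 0 for d in somatic_diffs):
        somatic_test = cross_individual_test(somatic_diffs)
    return RepertoireResult(report, positions, summaries, somatic_summaries,
                            germline_tests, somatic_test)
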
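"""Population-SNV codon substitution matrices and phosphosite selection.

From a table of single-nucleotide variants inside canonical coding
sequences the module builds:

* ``C`` — the observed 61x61 codon substitution matrix, each cell the count
  of row-to-column codon events normalised by the row codon's occurrences in
  the CDS set, diagonal completed so rows sum to 1;
* ``M`` — the 4x4 neutral nucleotide mutation matrix estimated only from
  third-position variants of the fourfold-degenerate codon families of
  valine, proline, threonine, alanine and glycine (third-position changes
  there are synonymous, hence approximately neutral);
* ``E`` — the expected codon matrix under independence of the three codon
  positions, E[c->c'] = M[c1->c1'] M[c2->c2'] M[c3->c3'], with stop-target
  mass dropped and the diagonal recompleted.

Phosphosite selection is scored per substitution edge (source codon set ->
target amino acid, single point mutations only) as r = log10(observed /
expected); |r| <= 1 is called neutral, r > 1 enriched, r < -1 depleted.
Serine sources are split into their TCN (S1) and AGY (S2) codon sets; the
headline contrast is the fold difference of the S2->T and S1->T ratios.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    SERINE_AGY,
    SERINE_TCN,
    STOP_CODONS,
    hamming,
)

SENSE_CODON_LIST = tuple(sorted(SENSE_CODONS))

#: fourfold-degenerate families whose third position is synonymous for any
#: base; restricted to the five amino acids with a single codon box
FOURFOLD_FAMILIES: dict[str, str] = {
    "V": "GT", "P": "CC", "T": "AC", "A": "GC", "G": "GG",
}
#: the third-position-degenerate quartets inside six-codon families,
#: excluded from the neutral model by default
SIXFOLD_QUARTETS: dict[str, str] = {"L": "CT", "S": "TC", "R": "CG"}


@dataclass
class SNVRecord:
    """A single-nucleotide variant in CDS coordinates (1-based)."""

    cds_id: str
    position: int
    ref: str
    alt: str
    high_quality: bool = True
    major_is_ref: bool = True

    def oriented(self) -> tuple[str, str]:
        """(major, minor) alleles — the substitution direction analysed."""
        return (self.ref, self.alt) if self.major_is_ref else (self.alt, self.ref)


@dataclass
class FilterSummary:
    n_input: int
    n_retained: int
    n_low_quality: int = 0
    n_outside_cds: int = 0
    n_stop_codon: int = 0
    n_ref_mismatch: int = 0

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0


@dataclass
class MappedSNV:
    cds_id: str
    codon_index: int      # 0-based codon within the CDS
    offset: int           # 0, 1, 2 within the codon
    source_codon: str     # major-allele codon
    target_codon: str     # minor-allele codon


def _codon_context(cds: str, position: int) -> tuple[int, int, str]:
    codon_index, offset = divmod(position - 1, 3)
    return codon_index, offset, cds[3 * codon_index:3 * codon_index + 3]


def filter_snvs(snvs: list[SNVRecord], cds_set: dict[str, str]
                ) -> tuple[list[MappedSNV], FilterSummary]:
    """Map SNVs to codon changes, keeping high-quality in-CDS sense variants.

    Variants outside any CDS, in stop codons, of low quality, or whose
    major allele disagrees with the CDS base are dropped and tallied.
    The mapped substitution is always major allele -> minor allele.
    """
    summary = FilterSummary(n_input=len(snvs), n_retained=0)
    mapped: list[MappedSNV] = []
    for snv in snvs:
        if not snv.high_quality:
            summary.n_low_quality += 1
            continue
        cds = cds_set.get(snv.cds_id)
        if cds is None or not 1 <= snv.position <= len(cds):
            summary.n_outside_cds += 1
            continue
        codon_index, offset, codon = _codon_context(cds, snv.position)
        if len(codon) != 3:
            summary.n_outside_cds += 1
            continue
        major, minor = snv.oriented()
        if codon[offset] != major:
            summary.n_ref_mismatch += 1
            continue
        target = codon[:offset] + minor + codon[offset + 1:]
        if codon in STOP_CODONS or target in STOP_CODONS:
            summary.n_stop_codon += 1
            continue
        mapped.append(MappedSNV(snv.cds_id, codon_index, offset, codon, target))
    summary.n_retained = len(mapped)
    return mapped, summary


def codon_occurrences(cds_set: dict[str, str]) -> Counter:
    """Sense-codon occurrence counts over a CDS set (stops ignored)."""
    occ: Counter = Counter()
    for cds in cds_set.values():
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if codon in SENSE_CODONS:
                occ[codon] += 1
    return occ


def build_codon_matrix(mapped: list[MappedSNV], cds_set: dict[str, str]
                       ) -> pd.DataFrame:
    """The observed 61x61 row-stochastic codon substitution matrix C.

    C[c, c'] = (c -> c' events) / (occurrences of c in the CDS set); the
    diagonal completes each row to 1.  Raises when a row's events exceed its
    occurrences (inconsistent input).
    """
    occ = codon_occurrences(cds_set)
    events: Counter = Counter((m.source_codon, m.target_codon) for m in mapped)
    c = pd.DataFrame(0.0, index=list(SENSE_CODON_LIST), columns=list(SENSE_CODON_LIST))
    for (src, dst), n in events.items():
        if occ[src] == 0:
            raise ValueError(f"events from codon {src} absent from the CDS set")
        c.loc[src, dst] = n / occ[src]
    off_diag = c.to_numpy().sum(axis=1) - np.diag(c.to_numpy())
    if np.any(off_diag > 1 + 1e-12):
        bad = [SENSE_CODON_LIST[i] for i in np.flatnonzero(off_diag > 1 + 1e-12)]
        raise ValueError(f"more events than occurrences for codons {bad}")
    arr = c.to_numpy()
    np.fill_diagonal(arr, 1.0 - off_diag)
    return pd.DataFrame(arr, index=c.index, columns=c.columns)


def neutral_site_mask(include_sixfold_quartets: bool = False) -> frozenset[str]:
    """Codon prefixes whose third position enters the neutral model."""
    prefixes = set(FOURFOLD_FAMILIES.values())
    if include_sixfold_quartets:
        prefixes |= set(SIXFOLD_QUARTETS.values())
    return frozenset(prefixes)


def build_neutral_model(
    mapped: list[MappedSNV],
    cds_set: dict[str, str],
    include_sixfold_quartets: bool = False,
) -> pd.DataFrame:
    """The 4x4 neutral nucleotide mutation matrix M.

    Only third-position variants inside the fourfold-degenerate families
    contribute.  M[b, b'] = (b -> b' events at those sites) / (occurrences of
    b at those sites); diagonal completed to row sum 1.  A base with no
    eligible site keeps an identity row (flagged by its zero off-diagonal).
    """
    prefixes = neutral_site_mask(include_sixfold_quartets)
    occ = Counter()
    for cds in cds_set.values():
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if codon[:2] in prefixes and codon in SENSE_CODONS:
                occ[codon[2]] += 1
    events = Counter()
    for m in mapped:
        if m.offset == 2 and m.source_codon[:2] in prefixes:
            events[(m.source_codon[2], m.target_codon[2])] += 1
    matrix = pd.DataFrame(0.0, index=list(BASES), columns=list(BASES))
    for (b, b2), n in events.items():
        if occ[b] == 0:
            raise ValueError(f"third-position events from base {b} with no occurrences")
        matrix.loc[b, b2] = n / occ[b]
    arr = matrix.to_numpy()
    np.fill_diagonal(arr, 1.0 - (arr.sum(axis=1) - np.diag(arr)))
    return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)


def neutral_fraction(mapped: list[MappedSNV],
                     include_sixfold_quartets: bool = False) -> float:
    """Fraction of all mapped SNVs at the neutral third positions."""
    prefixes = neutral_site_mask(include_sixfold_quartets)
    if not mapped:
        return 0.0
    hits = sum(m.offset == 2 and m.source_codon[:2] in prefixes for m in mapped)
    return hits / len(mapped)


def expected_matrix(nuc_matrix: pd.DataFrame) -> pd.DataFrame:
    """The expected codon matrix E under per-position independence.

    E[c, c'] is the product of the three per-position nucleotide mutation
    probabilities; mass on stop targets is dropped and the diagonal
    recompleted so every row sums to 1.
    """
    m = nuc_matrix.to_numpy()
    if not np.allclose(m.sum(axis=1), 1.0):
        raise ValueError("nucleotide matrix must be row-stochastic")
    base_idx = {b: i for i, b in enumerate(BASES)}
    n = len(SENSE_CODON_LIST)
    e = np.zeros((n, n))
    for i, src in enumerate(SENSE_CODON_LIST):
        for j, dst in enumerate(SENSE_CODON_LIST):
            e[i, j] = (m[base_idx[src[0]], base_idx[dst[0]]]
                       * m[base_idx[src[1]], base_idx[dst[1]]]
                       * m[base_idx[src[2]], base_idx[dst[2]]])
    off = e.sum(axis=1) - np.diag(e)
    np.fill_diagonal(e, 1.0 - off)
    return pd.DataFrame(e, index=list(SENSE_CODON_LIST), columns=list(SENSE_CODON_LIST))


@dataclass
class PhosphoSite:
    """A phosphorylatable residue (S, T or Y) with its encoding codon."""

    cds_id: str
    position: int          # 1-based amino-acid position in the CDS
    residue: str
    codon: str = ""
    phospho: bool = True

    def resolve_codon(self, cds_set: dict[str, str]) -> str:
        if self.codon:
            return self.codon
        cds = cds_set[self.cds_id]
        return cds[3 * (self.position - 1):3 * self.position]


def source_set_of(codon: str) -> str | None:
    """S1/S2/T/Y source label of a codon, None for other amino acids."""
    if codon in SERINE_TCN:
        return "S1"
    if codon in SERINE_AGY:
        return "S2"
    aa = CODON_TO_AA.get(codon)
    return aa if aa in ("T", "Y") else None


def _target_label(codon: str) -> str:
    if codon in SERINE_TCN:
        return "S1"
    if codon in SERINE_AGY:
        return "S2"
    return CODON_TO_AA[codon]


@dataclass
class SubstitutionEdge:
    """One source-set -> target-amino-acid edge of the substitution network."""

    source: str
    target: str
    observed: float
    expected: float
    ratio: float = field(init=False)     # log10(observed / expected)
    edge_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.expected == 0:
            self.ratio = math.inf if self.observed > 0 else math.nan
        elif self.observed == 0:
            self.ratio = -math.inf
        else:
            self.ratio = math.log10(self.observed / self.expected)
        if math.isnan(self.ratio) or -1 <= self.ratio <= 1:
            self.edge_class = "neutral"
        elif self.ratio > 1:
            self.edge_class = "enriched"
        else:
            self.edge_class = "depleted"

    @property
    def odds(self) -> float:
        """observed / expected (the antilog of ``ratio``)."""
        if self.expected == 0:
            return math.inf if self.observed > 0 else math.nan
        return self.observed / self.expected


def substitution_network(
    sites: list[PhosphoSite],
    mapped: list[MappedSNV],
    expected: pd.DataFrame,
    cds_set: dict[str, str],
) -> list[SubstitutionEdge]:
    """Single-point substitution edges from S1/S2/T/Y sites with selection scores.

    Observed flow per (source set, target amino acid) is the event count at
    the analysed sites normalised by the source set's codon occurrences among
    those sites; the expected flow aggregates E over the same source codons
    with the same occurrence weights, restricted to single-point-mutation
    targets.  r = log10(obs/exp); a source set with zero observed events
    scores -inf on all its edges.
    """
    site_lookup: dict[tuple[str, int], str] = {}
    source_occ: dict[str, Counter] = {}
    for site in sites:
        codon = site.resolve_codon(cds_set)
        source = source_set_of(codon)
        if source is None:
            continue
        site_lookup[(site.cds_id, site.position - 1)] = codon
        source_occ.setdefault(source, Counter())[codon] += 1

    observed: Counter = Counter()
    for m in mapped:
        codon = site_lookup.get((m.cds_id, m.codon_index))
        if codon is None or codon != m.source_codon:
            continue
        observed[(source_set_of(codon), _target_label(m.target_codon))] += 1

    edges: list[SubstitutionEdge] = []
    for source, occ in sorted(source_occ.items()):
        total_occ = sum(occ.values())
        # single-point-reachable targets from any member codon
        targets: dict[str, float] = {}
        for codon, n in occ.items():
            for dst in SENSE_CODON_LIST:
                if dst != codon and hamming(codon, dst) == 1:
                    label = _target_label(dst)
                    targets[label] = targets.get(label, 0.0) + n * expected.loc[codon, dst]
        for label in sorted(targets):
            obs = observed.get((source, label), 0) / total_occ
            exp = targets[label] / total_occ
            edges.append(SubstitutionEdge(source, label, obs, exp))
    return edges


def fold_difference(edges: list[SubstitutionEdge], source_a: str,
                    source_b: str, target: str) -> float:
    """(obs/exp) of source_a over (obs/exp) of source_b for a shared target.

    A suppression of source_b's edge by a factor k yields approximately k.
    Undefined or zero-flow edges propagate as inf/nan sentinels.
    """
    by_key = {(e.source, e.target): e for e in edges}
    try:
        edge_a, edge_b = by_key[(source_a, target)], by_key[(source_b, target)]
    except KeyError as err:
        raise ValueError(f"edge not present in network: {err}") from err
    odds_b = edge_b.odds
    if odds_b == 0 or math.isnan(odds_b) or math.isnan(edge_a.odds):
        return math.nan
    return edge_a.odds / odds_b
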
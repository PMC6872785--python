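"""Seeded generators for the inputs the analysis stages expect.

Three generators emulate the statistical structure of the real data sources
(deep vertebrate codon alignments, clonal B-cell-receptor repertoires with
region-biased mutation, and population exome SNV tables):

* :func:`simulate_msa` — per-column diversity regimes (conserved / diverse /
  hotspot) with a serine codon-set bias ``beta`` = P(serine encoded AGY);
* :func:`simulate_repertoire` — clonal repertoires whose germline serines
  are AGY-biased in CDR vs FWR and whose somatic mutations can be steered
  toward a region-preferred substitution group;
* :func:`simulate_exome` — SNVs drawn independently per CDS nucleotide from
  a true mutation matrix M*, thinned by per-edge selection factors, plus
  phosphosite placement on S/T/Y codons.

Every generator is a pure function of its spec (seed included): the random
stream is forked deterministically per position / individual, so reruns are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .genetic_code import (
    BASES,
    CODON_TO_AA,
    SENSE_CODONS,
    SERINE_AGY,
    SERINE_TCN,
    hamming,
)
from .phospho import PhosphoSite, SNVRecord, _target_label, source_set_of
from .repertoire import ReceptorRecord, RegionMask
from .split_blosum import AlignmentBlock

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

_SENSE_LIST = tuple(sorted(SENSE_CODONS))


_AGY = tuple(sorted(SERINE_AGY))
_TCN = tuple(sorted(SERINE_TCN))


def _serine_codon(rng: np.random.Generator, beta: float) -> str:
    """A serine codon: AGY with probability beta, TCN otherwise."""
    if rng.random() < beta:
        return _AGY[rng.integers(len(_AGY))]
    return _TCN[rng.integers(len(_TCN))]


def _codon_for(rng: np.random.Generator, aa: str, beta: float) -> str:
    if aa == "S":
        return _serine_codon(rng, beta)
    codons = AA_TO_CODONS[aa]
    return codons[rng.integers(len(codons))]


# ---------------------------------------------------------------------------
# multiple sequence alignments
# ---------------------------------------------------------------------------

@dataclass
class RegimeSpec:
    """One block of alignment columns sharing a diversity regime.

    ``concentration`` is the symmetric Dirichlet parameter for the column's
    amino-acid frequencies over ``pool`` — small values give skewed,
    low-diversity columns, large values near-uniform, high-diversity ones.
    ``beta`` is P(a serine is AGY-encoded) in this regime.
    """

    name: str                      # conserved | diverse | hotspot
    n_positions: int
    pool: str = "SGNPATVLID"
    concentration: float = 1.0
    beta: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.beta <= 1:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.n_positions < 0 or self.concentration <= 0:
            raise ValueError("n_positions must be >= 0 and concentration > 0")


@dataclass
class MsaSimSpec:
    n_sequences: int = 100
    regimes: list[RegimeSpec] = field(default_factory=lambda: [
        RegimeSpec("conserved", 50, concentration=0.1),
        RegimeSpec("diverse", 50, concentration=4.0),
    ])
    seed: int = 0


def simulate_msa(spec: MsaSimSpec) -> AlignmentBlock:
    """An aligned codon block with per-position diversity regimes.

    Column frequencies are drawn from a Dirichlet over the regime's pool;
    residues i.i.d. per sequence; serine codons follow the regime's beta.
    Columns appear in regime order, so column index maps back to a regime by
    cumulative position count.
    """
    children = np.random.SeedSequence(spec.seed).spawn(
        sum(r.n_positions for r in spec.regimes))
    columns: list[list[str]] = []
    child_iter = iter(children)
    for regime in spec.regimes:
        pool = list(regime.pool)
        for _ in range(regime.n_positions):
            rng = np.random.default_rng(next(child_iter))
            freqs = rng.dirichlet([regime.concentration] * len(pool))
            residues = rng.choice(pool, size=spec.n_sequences, p=freqs)
            columns.append([_codon_for(rng, aa, regime.beta) for aa in residues])
    sequences = ["".join(col[i] for col in columns) for i in range(spec.n_sequences)]
    return AlignmentBlock(sequences, ids=[f"seq{i}" for i in range(spec.n_sequences)])


def regime_labels(spec: MsaSimSpec) -> dict[int, str]:
    """Column index (0-based) -> regime name, matching simulate_msa order."""
    labels: dict[int, str] = {}
    idx = 0
    for regime in spec.regimes:
        for _ in range(regime.n_positions):
            labels[idx] = regime.name
            idx += 1
    return labels


# ---------------------------------------------------------------------------
# B-cell-receptor repertoires
# ---------------------------------------------------------------------------

@dataclass
class RepertoireSimSpec:
    """A cohort of clonal repertoires with region-dependent serine bias.

    ``beta_cdr`` / ``beta_fwr`` set P(germline serine is AGY) per region;
    ``target_bias_cdr`` / ``target_bias_fwr`` steer somatic mutations toward
    the region's preferred substitution group (GS2N in CDR, S1PA in FWR)
    with the given probability, otherwise a uniform single-nucleotide sense
    neighbour is drawn.
    """

    n_individuals: int = 20
    clones_per_individual: int = 30
    members_per_clone: int = 3
    beta_cdr: float = 0.5
    beta_fwr: float = 0.5
    serine_weight: float = 0.25
    pool: str = "SGNPATVLIKDEQ"
    mutation_rate: float = 0.02       # per codon per member
    target_bias_cdr: float = 0.0
    target_bias_fwr: float = 0.0
    mask: RegionMask = field(default_factory=RegionMask)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.members_per_clone < 1:
            raise ValueError("members_per_clone must be >= 1")
        for b in (self.beta_cdr, self.beta_fwr):
            if not 0 <= b <= 1:
                raise ValueError("beta must be in [0, 1]")


_NEIGHBORS: dict[str, tuple[str, ...]] = {
    c: tuple(d for d in _SENSE_LIST if hamming(c, d) == 1) for c in _SENSE_LIST
}


@lru_cache(maxsize=None)
def _preferred_neighbors(codon: str, region: str) -> tuple[str, ...]:
    from .enrichment import GS2N, S1PA
    group = GS2N if region == "CDR" else S1PA
    return tuple(d for d in _NEIGHBORS[codon] if group.contains(d))


def simulate_repertoire(spec: RepertoireSimSpec) -> list[ReceptorRecord]:
    """IMGT-numbered heavy-chain records, positions 1..106, gap-free."""
    n_positions = 106
    aa_pool = list(spec.pool)
    weights = np.array([spec.serine_weight if aa == "S" else
                        (1 - spec.serine_weight) / (len(aa_pool) - 1)
                        for aa in aa_pool])
    weights /= weights.sum()
    records: list[ReceptorRecord] = []
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_individuals)
    for ind_index, ind_seed in enumerate(seeds):
        rng = np.random.default_rng(ind_seed)
        individual = f"I{ind_index:02d}"
        for clone_idx in range(spec.clones_per_individual):
            v_call = f"IGHV{rng.integers(1, 8)}-{rng.integers(1, 10)}"
            j_call = f"IGHJ{rng.integers(1, 7)}"
            cdr3_length = int(rng.integers(6, 31))
            aa_draws = rng.choice(len(aa_pool), size=n_positions, p=weights)
            germline_codons = []
            for pos in range(1, n_positions + 1):
                region = spec.mask.region_of(pos) or "FWR"
                beta = spec.beta_cdr if region == "CDR" else spec.beta_fwr
                germline_codons.append(_codon_for(rng, aa_pool[aa_draws[pos - 1]], beta))
            germline = "".join(germline_codons)
            for _ in range(spec.members_per_clone):
                codons = list(germline_codons)
                for pos_idx in range(n_positions):
                    if rng.random() >= spec.mutation_rate:
                        continue
                    region = spec.mask.region_of(pos_idx + 1) or "FWR"
                    bias = (spec.target_bias_cdr if region == "CDR"
                            else spec.target_bias_fwr)
                    preferred = _preferred_neighbors(codons[pos_idx], region)
                    if preferred and bias > 0 and rng.random() < bias:
                        codons[pos_idx] = preferred[rng.integers(len(preferred))]
                    else:
                        options = _NEIGHBORS[codons[pos_idx]]
                        codons[pos_idx] = options[rng.integers(len(options))]
                records.append(ReceptorRecord(
                    individual, "".join(codons), germline,
                    v_call, j_call, cdr3_length))
    return records


def repertoire_to_frame(records: list[ReceptorRecord]) -> pd.DataFrame:
    """AIRR-rearrangement-like table of simulated records."""
    return pd.DataFrame({
        "individual": [r.individual for r in records],
        "sequence": [r.sequence for r in records],
        "germline": [r.germline for r in records],
        "v_call": [r.v_call for r in records],
        "j_call": [r.j_call for r in records],
        "cdr3_length": [r.cdr3_length for r in records],
        "imgt_start": [r.imgt_start for r in records],
    })


# ---------------------------------------------------------------------------
# exome SNVs under a known mutation matrix
# ---------------------------------------------------------------------------

def default_mutation_matrix() -> pd.DataFrame:
    """A transition-biased true mutation matrix M* (rows A, C, G, T).

    Off-diagonal mass 0.06 per base with transitions twice as likely as
    transversions — a deliberately polymorphism-dense regime so moderate
    synthetic CDS sizes yield well-populated matrices.
    """
    m = np.full((4, 4), 0.015)
    idx = {b: i for i, b in enumerate(BASES)}
    for a, b in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")):
        m[idx[a], idx[b]] = 0.03
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return pd.DataFrame(m, index=list(BASES), columns=list(BASES))


def edge_selection(source_label: str, target_label: str, factor: float
                   ) -> dict[tuple[str, str], float]:
    """Selection factors for every single-nt codon pair realising an edge.

    ``source_label`` is a source set (``S1``, ``S2``, ``T``, ``Y`` or an
    amino acid); ``target_label`` a (possibly split) target symbol.  E.g.
    ``edge_selection("S1", "T", 1/32)`` suppresses all TCN->ACN changes.
    """
    if factor < 0:
        raise ValueError("selection factor must be >= 0")
    out = {}
    for src in _SENSE_LIST:
        if (source_set_of(src) or CODON_TO_AA[src]) != source_label:
            continue
        for dst in _NEIGHBORS[src]:
            if _target_label(dst) == target_label:
                out[(src, dst)] = factor
    return out


@dataclass
class ExomeSimSpec:
    """SNVs from a known nucleotide matrix with optional planted selection.

    One independent draw from ``mut_matrix`` is made per CDS nucleotide (a
    diagonal draw produces no variant), so the neutral-model estimator is
    unbiased for M*.  ``n_codons`` sets the CDS length directly;
    :meth:`for_events` sizes it so the expected SNV count matches a target.
    ``selection`` maps (source codon, target codon) to a thinning factor in
    [0, 1]; ``phospho_fraction`` of S/T/Y codons are marked phosphosites.
    """

    n_codons: int = 50_000
    usage: dict[str, float] | None = None      # codon -> weight, sense only
    mut_matrix: pd.DataFrame = field(default_factory=default_mutation_matrix)
    selection: dict[tuple[str, str], float] = field(default_factory=dict)
    phospho_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.selection.values()):
            raise ValueError("selection factors must be >= 0")

    def codon_probs(self) -> np.ndarray:
        if self.usage is None:
            return np.full(len(_SENSE_LIST), 1.0 / len(_SENSE_LIST))
        w = np.array([self.usage.get(c, 0.0) for c in _SENSE_LIST], dtype=float)
        if w.sum() <= 0:
            raise ValueError("usage weights sum to zero")
        return w / w.sum()

    def expected_events_per_codon(self) -> float:
        probs = self.codon_probs()
        m = self.mut_matrix.to_numpy()
        idx = {b: i for i, b in enumerate(BASES)}
        per_codon = 0.0
        for codon, p in zip(_SENSE_LIST, probs):
            per_codon += p * sum(1.0 - m[idx[b], idx[b]] for b in codon)
        return per_codon

    @classmethod
    def for_events(cls, n_events: int, **kwargs) -> "ExomeSimSpec":
        spec = cls(n_codons=1, **kwargs)
        spec.n_codons = max(1, int(np.ceil(n_events / spec.expected_events_per_codon())))
        return spec


@dataclass
class SimulatedExome:
    cds_set: dict[str, str]
    snvs: list[SNVRecord]
    sites: list[PhosphoSite]


def simulate_exome(spec: ExomeSimSpec) -> SimulatedExome:
    """Draw a CDS, its SNVs and phosphosite annotations under the spec."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    codon_idx = rng.choice(len(_SENSE_LIST), size=spec.n_codons, p=spec.codon_probs())
    codons = np.array(_SENSE_LIST)[codon_idx]
    cds = "".join(codons)
    base_arr = np.frombuffer(cds.encode(), dtype="S1")
    base_codes = np.searchsorted(np.sort(np.frombuffer(b"ACGT", dtype="S1")), base_arr)
    # one draw from M* per nucleotide site; diagonal draw = no variant
    m = spec.mut_matrix.to_numpy()
    alt_codes = np.empty_like(base_codes)
    for b in range(4):
        mask = base_codes == b
        alt_codes[mask] = rng.choice(4, size=int(mask.sum()), p=m[b])
    variant_pos = np.flatnonzero(alt_codes != base_codes)

    snvs: list[SNVRecord] = []
    for pos in variant_pos:
        ref, alt = BASES[base_codes[pos]], BASES[alt_codes[pos]]
        codon_i, offset = divmod(int(pos), 3)
        src = codons[codon_i]
        dst = src[:offset] + alt + src[offset + 1:]
        factor = spec.selection.get((src, dst), 1.0)
        if factor < 1.0 and rng.random() >= factor:
            continue
        snvs.append(SNVRecord("synth", int(pos) + 1, ref, alt))

    sites: list[PhosphoSite] = []
    for i, codon in enumerate(codons):
        aa = CODON_TO_AA[codon]
        if aa in "STY" and (spec.phospho_fraction >= 1.0
                            or rng.random() < spec.phospho_fraction):
            sites.append(PhosphoSite("synth", i + 1, aa, codon))
    return SimulatedExome({"synth": cds}, snvs, sites)
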
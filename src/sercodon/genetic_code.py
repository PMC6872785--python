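"""The standard genetic code with a split amino-acid alphabet.

Serine is the only amino acid encoded by two disjoint codon sets — TCN
(written ``S1`` here, S-prime in print) and AGY (``S2``, S-double-prime) —
that cannot interconvert by a single point mutation.  Leucine and arginine
are also six-codon amino acids but their two sets (CTN/TTR and CGN/AGR) are
single-mutation neighbours.  This module encodes the code, the optional
splits, single-point-mutation neighbourhoods, and amino-acid property
classes; everything downstream builds on it.

Split symbols are plain ASCII strings (``S1``, ``S2``, ``L1``, ``L2``,
``R1``, ``R2``); Unicode primes are accepted by :func:`normalize_symbol`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

#: purine<->purine and pyrimidine<->pyrimidine single-base changes
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}

# Sense codons and stops from the standard code (translation table 1).
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: frozenset[str] = frozenset(CODON_TO_AA)

# The split codon sets.  Serine's two sets are disjoint at Hamming
# distance 2; leucine's and arginine's are at distance 1.
SERINE_TCN = frozenset({"TCT", "TCC", "TCA", "TCG"})
SERINE_AGY = frozenset({"AGT", "AGC"})
LEUCINE_CTN = frozenset({"CTT", "CTC", "CTA", "CTG"})
LEUCINE_TTR = frozenset({"TTA", "TTG"})
ARGININE_CGN = frozenset({"CGT", "CGC", "CGA", "CGG"})
ARGININE_AGR = frozenset({"AGA", "AGG"})

SPLIT_SETS: dict[str, frozenset[str]] = {
    "S1": SERINE_TCN,
    "S2": SERINE_AGY,
    "L1": LEUCINE_CTN,
    "L2": LEUCINE_TTR,
    "R1": ARGININE_CGN,
    "R2": ARGININE_AGR,
}

#: split symbol -> the unsplit amino-acid letter
SPLIT_BASE_AA: dict[str, str] = {
    "S1": "S", "S2": "S", "L1": "L", "L2": "L", "R1": "R", "R2": "R",
}

AMINO_ACIDS = tuple(sorted(set(CODON_TO_AA.values())))

_UNICODE_ALIASES = {
    "S′": "S1", "S″": "S2", "S''": "S2", "S'": "S1",
    "L′": "L1", "L″": "L2", "L''": "L2", "L'": "L1",
    "R′": "R1", "R″": "R2", "R''": "R2", "R'": "R1",
}


def normalize_symbol(symbol: str) -> str:
    """Map prime-notation aliases (S', S'', Unicode primes) to ASCII S1/S2."""
    return _UNICODE_ALIASES.get(symbol, symbol)


class StopCodonError(ValueError):
    """Raised when a stop codon is passed where a sense codon is required."""


def validate_codon(codon: str) -> str:
    """Uppercase and validate a 3-letter ACGT codon; returns the normal form."""
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in BASES for b in c):
        raise ValueError(f"not a valid DNA codon: {codon!r}")
    return c


@dataclass(frozen=True)
class SplitConfig:
    """Which six-codon amino acids are split into their two codon sets."""

    split_serine: bool = False
    split_leucine: bool = False
    split_arginine: bool = False

    def active_splits(self) -> tuple[str, ...]:
        out = []
        if self.split_serine:
            out += ["S1", "S2"]
        if self.split_leucine:
            out += ["L1", "L2"]
        if self.split_arginine:
            out += ["R1", "R2"]
        return tuple(out)

    def alphabet(self) -> tuple[str, ...]:
        """The symbol alphabet under this configuration, sorted."""
        split = self.active_splits()
        dropped = {SPLIT_BASE_AA[s] for s in split}
        return tuple(sorted([a for a in AMINO_ACIDS if a not in dropped] + list(split)))


@dataclass(frozen=True)
class SplitSymbol:
    """A symbol of the (possibly) split alphabet with its unsplit letter."""

    symbol: str
    base_aa: str


def base_aa(symbol: str) -> str:
    """Collapse a split symbol to its standard amino-acid letter."""
    symbol = normalize_symbol(symbol)
    return SPLIT_BASE_AA.get(symbol, symbol)


def translate(codon: str, config: SplitConfig = SplitConfig()) -> SplitSymbol:
    """Translate a sense codon under a split configuration.

    With all split flags off this is the standard genetic code.  Stop codons
    raise :class:`StopCodonError`; malformed codons raise ``ValueError``.
    """
    c = validate_codon(codon)
    if c in STOP_CODONS:
        raise StopCodonError(f"stop codon: {c}")
    aa = CODON_TO_AA[c]
    for sym in config.active_splits():
        if c in SPLIT_SETS[sym]:
            return SplitSymbol(sym, aa)
    return SplitSymbol(aa, aa)


@dataclass(frozen=True)
class NeighborSet:
    """Sense neighbours (codon -> split symbol) and stop neighbours."""

    sense: dict[str, SplitSymbol]
    stops: frozenset[str]

    def symbols(self) -> frozenset[str]:
        return frozenset(s.symbol for s in self.sense.values())


def single_mutation_neighbors(
    codon: str,
    config: SplitConfig = SplitConfig(),
    transitions_only: bool = False,
    positions: tuple[int, ...] = (0, 1, 2),
) -> NeighborSet:
    """All codons one point mutation away from ``codon``.

    With ``transitions_only`` the mutation is restricted to A<->G / C<->T,
    which yields exactly one neighbour per position.  ``positions`` restricts
    which codon positions (0-based) may mutate.  Stop-codon neighbours are
    reported separately rather than silently dropped.
    """
    c = validate_codon(codon)
    if c in STOP_CODONS:
        raise StopCodonError(f"stop codon: {c}")
    sense: dict[str, SplitSymbol] = {}
    stops: set[str] = set()
    for pos in positions:
        ref = c[pos]
        alts = [TRANSITIONS[ref]] if transitions_only else [b for b in BASES if b != ref]
        for alt in alts:
            mutant = c[:pos] + alt + c[pos + 1:]
            if mutant in STOP_CODONS:
                stops.add(mutant)
            else:
                sense[mutant] = translate(mutant, config)
    return NeighborSet(sense, frozenset(stops))


def hamming(codon_a: str, codon_b: str) -> int:
    return sum(a != b for a, b in zip(codon_a, codon_b, strict=True))


def min_interset_distance(set_a, set_b) -> int:
    """Minimum Hamming distance over all cross pairs of two codon sets."""
    a = [validate_codon(c) for c in set_a]
    b = [validate_codon(c) for c in set_b]
    if not a or not b:
        raise ValueError("codon sets must be non-empty")
    return min(hamming(x, y) for x, y in product(a, b))


# ---------------------------------------------------------------------------
# Amino-acid property classes.
#
# Hydrophobicity in three grades plus a beta-turn-propensity flag.  The
# substitution groups of interest are: the AGY-serine transition neighbourhood
# {G, S2, N} — neutral-hydrophobicity, beta-turn formers — and the TCN-serine
# first-position neighbourhood {S1, P, A} — generally neutral.  This table is
# a conventional literature classification, shipped for annotation only; no
# statistic in the package depends on it.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyClass:
    hydrophobicity: str  # "hydrophobic" | "neutral" | "hydrophilic"
    beta_turn: bool


PROPERTY_CLASSES: dict[str, PropertyClass] = {
    **{aa: PropertyClass("hydrophobic", False) for aa in "FILMVWC"},
    **{aa: PropertyClass("hydrophilic", False) for aa in "EKRHQ"},
    **{aa: PropertyClass("neutral", False) for aa in "ATY"},
    "G": PropertyClass("neutral", True),
    "S": PropertyClass("neutral", True),
    "N": PropertyClass("neutral", True),
    "P": PropertyClass("neutral", True),
    "D": PropertyClass("hydrophilic", True),
}
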
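"""BLOSUM-style substitution matrices over the split amino-acid alphabet.

Pair frequencies are accumulated column-by-column over blocks of aligned,
in-frame coding sequences, exactly as in the classic BLOcks SUbstitution
Matrix construction, except that codons — not amino-acid letters — are read
from the alignment, so serine (and optionally leucine/arginine) columns can
be scored separately for their two codon sets.  Scores are half-bit integer
log-odds s_ij = round(2 * log2(q_ij / e_ij)).

Splitting then collapsing the split rows/columns of the pair-count matrix
recovers the unsplit counts exactly; tests rely on this identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    STOP_CODONS,
    SplitConfig,
    base_aa,
    translate,
)

GAP_CODON = "---"

#: sentinel score for q_ij = 0 cells when no pseudocount is used
FLOOR_SCORE = -99


@dataclass
class AlignmentBlock:
    """Equal-length, in-frame aligned coding sequences (gaps as ``-``)."""

    sequences: list[str]
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment block is empty")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_codon_columns(self) -> int:
        return len(self.sequences[0]) // 3

    def codon_column(self, index: int) -> list[str]:
        """Codons of column ``index`` (0-based), one per sequence, gaps included."""
        start = 3 * index
        return [s[start:start + 3] for s in self.sequences]


def _column_symbols(codons: Sequence[str], config: SplitConfig) -> list[str | None]:
    """Split symbols per sequence; None for gapped or stop-contributing rows."""
    out: list[str | None] = []
    for c in codons:
        if "-" in c or c in STOP_CODONS:
            out.append(None)
        else:
            out.append(translate(c, config).symbol)
    return out


def _cluster_weights(block: AlignmentBlock, config: SplitConfig,
                     identity: float) -> tuple[np.ndarray, np.ndarray]:
    """Henikoff-style single-linkage identity clustering.

    Sequences whose pairwise symbol identity is >= ``identity`` fall into one
    cluster; each sequence gets weight 1/|cluster|.  Returns (weights,
    cluster labels).  Pairs within one cluster are not counted.
    """
    n = len(block.sequences)
    symbols = [
        _column_symbols(block.codon_column(j), config)
        for j in range(block.n_codon_columns)
    ]
    # pairwise identity over columns where both sequences have a symbol
    adj = np.zeros((n, n), dtype=bool)
    for i, j in combinations(range(n), 2):
        same = total = 0
        for col in symbols:
            if col[i] is not None and col[j] is not None:
                total += 1
                same += col[i] == col[j]
        if total and same / total >= identity:
            adj[i, j] = adj[j, i] = True
    labels = np.full(n, -1)
    label = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        stack = [start]
        labels[start] = label
        while stack:
            cur = stack.pop()
            for nxt in np.flatnonzero(adj[cur]):
                if labels[nxt] < 0:
                    labels[nxt] = label
                    stack.append(nxt)
        label += 1
    sizes = np.bincount(labels)
    weights = 1.0 / sizes[labels]
    return weights, labels


@dataclass
class PairCountMatrix:
    """Symmetric pair counts with derived target/background frequencies.

    ``f`` holds unordered pair counts (possibly fractional under clustering
    weights).  q_ij are pair frequencies normalised over unordered pairs,
    p_i = q_ii + sum_{j != i} q_ij / 2 the background frequencies, and
    e_ii = p_i^2, e_ij = 2 p_i p_j the expected pair frequencies.
    """

    alphabet: tuple[str, ...]
    f: pd.DataFrame
    config: SplitConfig = field(default_factory=SplitConfig)

    @property
    def total(self) -> float:
        # diagonal once + each off-diagonal unordered pair once
        upper = np.triu(self.f.to_numpy())
        return float(upper.sum())

    def q(self) -> pd.DataFrame:
        total = self.total
        if total == 0:
            raise ValueError("pair-count matrix is empty (all-gap input?)")
        return self.f / total

    def p(self) -> pd.Series:
        q = self.q()
        diag = pd.Series(np.diag(q.to_numpy()), index=q.index)
        off = q.sum(axis=1) - diag
        return diag + off / 2.0

    def e(self) -> pd.DataFrame:
        p = self.p().to_numpy()
        e = 2.0 * np.outer(p, p)
        np.fill_diagonal(e, p ** 2)
        return pd.DataFrame(e, index=self.f.index, columns=self.f.columns)

    def with_pseudocount(self, pseudocount: float) -> "PairCountMatrix":
        return PairCountMatrix(self.alphabet, self.f + pseudocount, self.config)


def count_pairs(
    blocks: Iterable[AlignmentBlock],
    config: SplitConfig = SplitConfig(),
    cluster_identity: float | None = None,
) -> PairCountMatrix:
    """Accumulate unordered symbol-pair counts over all columns of all blocks.

    A gap or stop codon removes that sequence from that column; columns with
    fewer than two remaining sequences contribute nothing.  With
    ``cluster_identity`` set, sequences are clustered per block at that
    identity, weighted 1/cluster-size, and within-cluster pairs skipped.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no alignment blocks given")
    if cluster_identity is not None and not 0 < cluster_identity <= 1:
        raise ValueError("cluster_identity must be in (0, 1]")
    alphabet = config.alphabet()
    index = {s: i for i, s in enumerate(alphabet)}
    f = np.zeros((len(alphabet), len(alphabet)))
    for block in blocks:
        n = len(block.sequences)
        if cluster_identity is not None and n > 1:
            weights, labels = _cluster_weights(block, config, cluster_identity)
        else:
            weights, labels = np.ones(n), np.arange(n)
        for col_idx in range(block.n_codon_columns):
            symbols = _column_symbols(block.codon_column(col_idx), config)
            present = [i for i, s in enumerate(symbols) if s is not None]
            if len(present) < 2:
                continue
            for i, j in combinations(present, 2):
                if labels[i] == labels[j] and i != j and cluster_identity is not None:
                    continue
                a, b = index[symbols[i]], index[symbols[j]]
                w = weights[i] * weights[j]
                f[a, b] += w
                if a != b:
                    f[b, a] += w
    if f.sum() == 0:
        raise ValueError("no countable pairs (all-gap or depth-1 data)")
    frame = pd.DataFrame(f, index=list(alphabet), columns=list(alphabet))
    return PairCountMatrix(alphabet, frame, config)


def collapse_pair_counts(counts: PairCountMatrix) -> PairCountMatrix:
    """Merge split rows/columns of f back onto the unsplit 20-letter alphabet.

    Works on unordered pair counts: a cross pair such as (S1, S2) collapses
    onto the (S, S) diagonal exactly once.
    """
    mapping = {s: base_aa(s) for s in counts.alphabet}
    alphabet = tuple(sorted(set(mapping.values())))
    index = {s: i for i, s in enumerate(alphabet)}
    f = np.zeros((len(alphabet), len(alphabet)))
    symbols = list(counts.alphabet)
    for i, a in enumerate(symbols):
        for b in symbols[i:]:
            count = counts.f.loc[a, b]
            if count == 0:
                continue
            x, y = index[mapping[a]], index[mapping[b]]
            f[x, y] += count
            if x != y:
                f[y, x] += count
    frame = pd.DataFrame(f, index=list(alphabet), columns=list(alphabet))
    return PairCountMatrix(alphabet, frame, SplitConfig())


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class SubstitutionMatrix:
    """Integer half-bit log-odds scores plus the raw real-valued matrix."""

    alphabet: tuple[str, ...]
    scores: pd.DataFrame           # integer half-bits
    raw: pd.DataFrame              # 2*log2(q/e), -inf where q == 0
    undefined: pd.DataFrame        # True where background p_i or p_j is 0

    def score(self, a: str, b: str) -> int:
        return int(self.scores.loc[a, b])


def log_odds(counts: PairCountMatrix, pseudocount: float = 0.0,
             floor: int = FLOOR_SCORE) -> SubstitutionMatrix:
    """Half-bit log-odds scores from a pair-count matrix.

    ``pseudocount`` (Laplace) is added to every f_ij before normalisation
    when positive.  With pseudocount 0, cells with q_ij = 0 get the ``floor``
    sentinel; cells whose background frequency is 0 are flagged undefined.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount > 0:
        counts = counts.with_pseudocount(pseudocount)
    q = counts.q().to_numpy()
    p = counts.p().to_numpy()
    e = counts.e().to_numpy()
    undefined = np.logical_or.outer(p == 0, p == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = 2.0 * np.log2(q / e)
    raw[undefined] = np.nan
    scores = np.full(raw.shape, floor, dtype=int)
    finite = np.isfinite(raw)
    scores[finite] = [round_half_away(v) for v in raw[finite]]
    idx = list(counts.alphabet)
    return SubstitutionMatrix(
        counts.alphabet,
        pd.DataFrame(scores, index=idx, columns=idx),
        pd.DataFrame(raw, index=idx, columns=idx),
        pd.DataFrame(undefined, index=idx, columns=idx),
    )


@dataclass
class MatrixComparison:
    """Per-cell change classes of a split matrix against its unsplit reference.

    Classes are ``increase``, ``decrease``, ``sign_flip`` (sign changed
    between strictly positive and strictly negative) and ``unchanged``;
    exactly one per cell.  Each split-alphabet cell is compared against the
    reference cell of its collapsed symbols.
    """

    classes: pd.DataFrame
    test: SubstitutionMatrix
    reference: SubstitutionMatrix

    def cells(self, change_class: str) -> list[tuple[str, str]]:
        mask = self.classes == change_class
        return [(a, b) for a in mask.index for b in mask.columns if mask.loc[a, b]]


def classify_change(test_value: float, reference_value: float) -> str:
    if test_value == reference_value:
        return "unchanged"
    if (test_value > 0) != (reference_value > 0) and test_value != 0 and reference_value != 0:
        return "sign_flip"
    return "increase" if test_value > reference_value else "decrease"


def compare_matrices(
    test: SubstitutionMatrix,
    reference: SubstitutionMatrix,
    collapse_map: Mapping[str, str] | None = None,
) -> MatrixComparison:
    """Classify every cell of ``test`` against its collapsed reference cell."""
    if collapse_map is None:
        collapse_map = {s: base_aa(s) for s in test.alphabet}
    missing = [s for s in test.alphabet if collapse_map.get(s) not in reference.alphabet]
    if missing:
        raise ValueError(f"symbols not mappable onto reference alphabet: {missing}")
    classes = pd.DataFrame(index=test.scores.index, columns=test.scores.columns, dtype=object)
    for a in test.alphabet:
        for b in test.alphabet:
            ref = reference.scores.loc[collapse_map[a], collapse_map[b]]
            classes.loc[a, b] = classify_change(test.scores.loc[a, b], ref)
    return MatrixComparison(classes, test, reference)


def brute_force_pair_counts(block: AlignmentBlock,
                            config: SplitConfig = SplitConfig()) -> dict[frozenset, float]:
    """Exhaustive per-column enumeration of all sequence pairs (test oracle).

    Returns unordered-pair counts keyed by frozenset of symbols (a singleton
    frozenset for identical pairs).  No clustering.
    """
    out: dict[frozenset, float] = {}
    for col_idx in range(block.n_codon_columns):
        symbols = [s for s in _column_symbols(block.codon_column(col_idx), config)
                   if s is not None]
        for x, y in combinations(symbols, 2):
            key = frozenset((x, y))
            out[key] = out.get(key, 0.0) + 1.0
    return out
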
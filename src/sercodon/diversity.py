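"""Per-column order-1 diversity and the "meaningful amino acid" call.

At each alignment column the order-1 Hill number D = exp(Shannon entropy)
gives the effective number of equally common amino acids.  The n = round(D)
most abundant amino acids (ties at rank n included) form the meaningful set;
a position is serine-meaningful when S is in that set.  Diversity is always
computed over the 20 unsplit amino acids — codon-set splits change how a
serine is *classified* downstream, never how diverse a column is.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genetic_code import STOP_CODONS, SplitConfig, translate
from .split_blosum import AlignmentBlock, round_half_away


def hill_diversity_q1(counts) -> float:
    """Order-1 Hill number exp(-sum p_i ln p_i) of a count/frequency vector."""
    values = np.asarray(
        list(counts.values()) if isinstance(counts, (dict, Counter)) else counts,
        dtype=float,
    )
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("diversity of an all-zero count vector is undefined")
    p = values / values.sum()
    return float(np.exp(-np.dot(p, np.log(p))))


@dataclass
class PositionProfile:
    """Amino-acid composition of one alignment column.

    ``aa_counts`` are unsplit 20-letter counts; ``split_counts`` additionally
    separate serine (and any other configured split) by codon set, for the
    downstream substitution-group classification.  Positions are 0-based
    internally; ``position`` + 1 is the reported coordinate.
    """

    position: int
    aa_counts: Counter = field(default_factory=Counter)
    split_counts: Counter = field(default_factory=Counter)

    @property
    def depth(self) -> int:
        return sum(self.aa_counts.values())

    def frequencies(self) -> dict[str, float]:
        depth = self.depth
        return {aa: c / depth for aa, c in self.aa_counts.items()}

    @property
    def diversity(self) -> float:
        return hill_diversity_q1(self.aa_counts)

    @property
    def n_meaningful(self) -> int:
        """n = round-half-away-from-zero(D), never below 1."""
        return max(1, round_half_away(self.diversity))

    def meaningful_set(self) -> frozenset[str]:
        return meaningful_set(self)

    @property
    def serine_meaningful(self) -> bool:
        return "S" in self.meaningful_set()


def meaningful_set(profile: PositionProfile) -> frozenset[str]:
    """The n most abundant amino acids, expanded to include rank-n ties."""
    n = profile.n_meaningful
    ranked = profile.aa_counts.most_common()
    if len(ranked) <= n:
        return frozenset(aa for aa, _ in ranked)
    cutoff = ranked[n - 1][1]
    return frozenset(aa for aa, count in ranked if count >= cutoff)


def serine_meaningful(profile: PositionProfile) -> bool:
    """True iff serine (S1 and/or S2 pooled) is a meaningful amino acid."""
    return profile.serine_meaningful


def profiles_from_alignment(
    block: AlignmentBlock,
    config: SplitConfig = SplitConfig(split_serine=True),
) -> list[PositionProfile]:
    """One profile per codon column; gaps and stops excluded from counts.

    Columns of depth 0 are skipped.  ``config`` controls only the split
    symbol counts carried for downstream classification.
    """
    profiles = []
    for idx in range(block.n_codon_columns):
        profile = PositionProfile(idx)
        for codon in block.codon_column(idx):
            if "-" in codon or codon in STOP_CODONS:
                continue
            sym = translate(codon, config)
            profile.aa_counts[sym.base_aa] += 1
            profile.split_counts[sym.symbol] += 1
        if profile.depth > 0:
            profiles.append(profile)
    return profiles


def tukey_inliers(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean mask of values inside [Q1 - k*IQR, Q3 + k*IQR]."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - k * iqr) & (values <= q3 + k * iqr)


@dataclass
class QuartilePartition:
    """Diversity extremes after Tukey outlier exclusion.

    ``high``/``low`` hold the indices (into the input list) of positions whose
    diversity is strictly above the upper / below the lower quartile; ``mid``
    the rest of the inliers.  Quartiles use linear interpolation.
    """

    high: list[int]
    mid: list[int]
    low: list[int]
    lower_quartile: float
    upper_quartile: float
    outliers: list[int]


def diversity_quartiles(diversities) -> QuartilePartition:
    """Partition positions into high/mid/low diversity by quartile.

    Accepts PositionProfiles or plain diversity values (>= 4 of them).
    Outliers by the Tukey 1.5*IQR rule are excluded before the quartiles are
    computed and belong to no group.
    """
    values = np.asarray(
        [d.diversity if isinstance(d, PositionProfile) else float(d) for d in diversities]
    )
    if values.size < 4:
        raise ValueError("need at least 4 positions for a quartile partition")
    inlier_mask = tukey_inliers(values)
    inliers = values[inlier_mask]
    q1, q3 = np.percentile(inliers, [25, 75])
    high, mid, low, outliers = [], [], [], []
    for i, (v, ok) in enumerate(zip(values, inlier_mask)):
        if not ok:
            outliers.append(i)
        elif v > q3:
            high.append(i)
        elif v < q1:
            low.append(i)
        else:
            mid.append(i)
    return QuartilePartition(high, mid, low, float(q1), float(q3), outliers)
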
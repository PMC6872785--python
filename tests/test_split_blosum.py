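"""Pair counting and log-odds scoring over the split alphabet."""

import numpy as np
import pytest

from sercodon.genetic_code import SplitConfig
from sercodon.split_blosum import (
    AlignmentBlock,
    PairCountMatrix,
    brute_force_pair_counts,
    classify_change,
    collapse_pair_counts,
    compare_matrices,
    count_pairs,
    log_odds,
    round_half_away,
)

SPLIT_S = SplitConfig(split_serine=True)

# codons used to assemble random test blocks: serine both sets, its
# substitution-group neighbours, and fillers
_CODON_POOL = ["TCT", "TCA", "AGT", "AGC", "GGT", "AAT", "CCT", "GCT",
               "GTT", "ATT", "---", "TAA"]


def random_block(rng, max_seqs=5, max_cols=4):
    n = rng.integers(2, max_seqs + 1)
    w = rng.integers(1, max_cols + 1)
    seqs = ["".join(rng.choice(_CODON_POOL) for _ in range(w)) for _ in range(n)]
    return AlignmentBlock(seqs)


class TestCountPairs:
    def test_worked_single_column_example(self):
        """Column [A, A, S1]: three unordered pairs, hand-enumerated."""
        block = AlignmentBlock(["GCT", "GCT", "TCT"])
        pcm = count_pairs([block], SPLIT_S)
        assert pcm.f.loc["A", "A"] == 1
        assert pcm.f.loc["A", "S1"] == 2
        q = pcm.q()
        assert q.loc["A", "A"] == pytest.approx(1 / 3)
        assert q.loc["A", "S1"] == pytest.approx(2 / 3)
        p = pcm.p()
        assert p["A"] == pytest.approx(2 / 3)
        assert p["S1"] == pytest.approx(1 / 3)

    def test_identical_sequences_only_diagonal(self):
        block = AlignmentBlock(["GCTTCAGGT", "GCTTCAGGT"])
        pcm = count_pairs([block], SPLIT_S)
        off_diag = pcm.f.to_numpy() - np.diag(np.diag(pcm.f.to_numpy()))
        assert off_diag.sum() == 0
        assert np.trace(pcm.f.to_numpy()) == block.n_codon_columns

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_oracle(self, seed):
        """f matches exhaustive per-column pair enumeration on small blocks."""
        rng = np.random.default_rng(seed)
        block = random_block(rng)
        try:
            pcm = count_pairs([block], SPLIT_S)
        except ValueError:
            assert not brute_force_pair_counts(block, SPLIT_S)
            return
        oracle = brute_force_pair_counts(block, SPLIT_S)
        for a in pcm.alphabet:
            for b in pcm.alphabet:
                if a <= b:
                    key = frozenset((a, b))
                    assert pcm.f.loc[a, b] == oracle.get(key, 0.0), (a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_collapse_invariance(self, seed):
        """Counting split then merging rows/cols equals counting unsplit."""
        rng = np.random.default_rng(100 + seed)
        block = random_block(rng, max_seqs=6, max_cols=5)
        try:
            split = count_pairs([block], SplitConfig(True, True, True))
        except ValueError:
            return
        unsplit = count_pairs([block], SplitConfig())
        collapsed = collapse_pair_counts(split)
        shared = sorted(set(collapsed.alphabet) | set(unsplit.alphabet))
        a = collapsed.f.reindex(index=shared, columns=shared, fill_value=0.0)
        b = unsplit.f.reindex(index=shared, columns=shared, fill_value=0.0)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_gap_removes_sequence_from_column(self):
        block = AlignmentBlock(["GCT", "---", "GCT"])
        pcm = count_pairs([block])
        assert pcm.f.loc["A", "A"] == 1
        assert pcm.total == 1

    def test_stop_codon_excludes_sequence_at_column(self):
        block = AlignmentBlock(["GCT", "TAA", "GCT"])
        pcm = count_pairs([block])
        assert pcm.f.loc["A", "A"] == 1

    def test_depth_one_column_contributes_nothing(self):
        with pytest.raises(ValueError, match="no countable pairs"):
            count_pairs([AlignmentBlock(["GCT", "---"])])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            AlignmentBlock(["GCT", "GCTGCT"])

    def test_symmetry_and_normalization(self):
        rng = np.random.default_rng(7)
        block = random_block(rng, max_seqs=6, max_cols=6)
        pcm = count_pairs([block], SPLIT_S)
        f = pcm.f.to_numpy()
        assert np.allclose(f, f.T)
        assert pcm.q().to_numpy()[np.triu_indices(len(pcm.alphabet))].sum() == pytest.approx(1.0)
        p = pcm.p()
        assert p.sum() == pytest.approx(1.0)
        e = pcm.e()
        assert np.allclose(e.to_numpy(), e.to_numpy().T)

    def test_clustering_halves_identical_sequence_weights(self):
        # two identical sequences cluster together; their mutual pair is
        # skipped and their pairs with the third sequence carry weight 1/2
        block = AlignmentBlock(["GCT", "GCT", "TCT"])
        pcm = count_pairs([block], SPLIT_S, cluster_identity=1.0)
        assert pcm.f.loc["A", "A"] == 0
        assert pcm.f.loc["A", "S1"] == pytest.approx(1.0)  # 2 pairs x 1/2


class TestLogOdds:
    def test_worked_example_scores(self):
        """[A, A, S1] column: s_AA = -1, s_{A,S1} = +1 in half-bits."""
        pcm = count_pairs([AlignmentBlock(["GCT", "GCT", "TCT"])], SPLIT_S)
        matrix = log_odds(pcm)
        assert matrix.score("A", "A") == -1
        assert matrix.score("A", "S1") == 1

    def test_single_symbol_scores_zero(self):
        # q == e exactly when only one symbol is present
        pcm = count_pairs([AlignmentBlock(["GCT", "GCT", "GCT"])])
        assert log_odds(pcm).score("A", "A") == 0

    def test_doubling_counts_leaves_scores_unchanged(self):
        pcm = count_pairs([AlignmentBlock(["GCTTCA", "GCTAGT", "TCTAGT"])], SPLIT_S)
        doubled = PairCountMatrix(pcm.alphabet, pcm.f * 2, pcm.config)
        assert log_odds(pcm).scores.equals(log_odds(doubled).scores)

    def test_zero_cells_get_floor_sentinel(self):
        pcm = count_pairs([AlignmentBlock(["GCT", "GCT", "TCT"])], SPLIT_S)
        matrix = log_odds(pcm)
        assert matrix.score("G", "G") == -99

    def test_pseudocount_removes_floor(self):
        pcm = count_pairs([AlignmentBlock(["GCT", "GCT", "TCT"])], SPLIT_S)
        matrix = log_odds(pcm, pseudocount=0.5)
        assert (matrix.scores.to_numpy() > -99).all()

    def test_negative_pseudocount_rejected(self):
        pcm = count_pairs([AlignmentBlock(["GCT", "GCT"])])
        with pytest.raises(ValueError):
            log_odds(pcm, pseudocount=-1)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(1.49) == 1
        assert round_half_away(-2.5) == -3


class TestCompare:
    @pytest.mark.parametrize("test,ref,expected", [
        (-2, 3, "sign_flip"),
        (5, 5, "unchanged"),
        (4, 2, "increase"),
        (1, 2, "decrease"),
        (0, 2, "decrease"),   # zero is not a sign flip
    ])
    def test_change_classes(self, test, ref, expected):
        assert classify_change(test, ref) == expected

    def test_split_context_signs(self):
        """S2 co-occurring with G/N and S1 with P/A flips the serine signs.

        On a block where AGY-serine columns also hold glycine/asparagine and
        TCN-serine columns hold proline/alanine, the split matrix scores
        s(S2, G) > 0 while s(S1, G) < 0.
        """
        s2_col = ["AGT", "AGC", "GGT", "AAT"]   # S2 with G/N
        s1_col = ["TCT", "TCA", "CCT", "GCT"]   # S1 with P/A
        seqs = ["".join(cod) for cod in zip(s2_col, s1_col)]
        # replicate columns to stabilise frequencies
        block = AlignmentBlock([s * 5 for s in seqs])
        matrix = log_odds(count_pairs([block], SPLIT_S), pseudocount=0.01)
        assert matrix.raw.loc["S2", "G"] > 0
        assert matrix.raw.loc["S1", "G"] < 0
        assert matrix.raw.loc["S1", "P"] > 0
        assert matrix.raw.loc["S2", "P"] < 0

    def test_synonymous_diagonal_beats_cross_set(self):
        """With no cross-set interchange, s(S1,S1) and s(S2,S2) > s(S1,S2)."""
        block = AlignmentBlock(["TCTAGT" * 3, "TCCAGC" * 3, "TCAAGT" * 3,
                                "GCTGGT" * 3])
        matrix = log_odds(count_pairs([block], SPLIT_S), pseudocount=0.01)
        assert matrix.raw.loc["S1", "S1"] > matrix.raw.loc["S1", "S2"]
        assert matrix.raw.loc["S2", "S2"] > matrix.raw.loc["S1", "S2"]

    def test_comparison_against_collapsed_reference(self):
        block = AlignmentBlock(["TCTGCT", "AGTGCT", "TCAGCT"])
        split = log_odds(count_pairs([block], SPLIT_S))
        unsplit = log_odds(count_pairs([block], SplitConfig()))
        comparison = compare_matrices(split, unsplit)
        assert set(np.unique(comparison.classes.to_numpy())) <= {
            "increase", "decrease", "sign_flip", "unchanged"}
        # A-A is identical in both builds
        assert comparison.classes.loc["A", "A"] == "unchanged"

    def test_unmappable_symbol_rejected(self):
        block = AlignmentBlock(["TCTGCT", "AGTGCT", "TCAGCT"])
        split = log_odds(count_pairs([block], SPLIT_S))
        unsplit = log_odds(count_pairs([block], SplitConfig()))
        with pytest.raises(ValueError, match="not mappable"):
            compare_matrices(split, unsplit, collapse_map={s: "?" for s in split.alphabet})
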
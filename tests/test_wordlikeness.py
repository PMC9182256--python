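import string

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexcat import (
    Lexicon,
    build_table,
    coltheart_n,
    edit_distance,
    ngram_score,
    old20,
    synth_lexicon,
)
from lexcat.stimuli import StimulusItem, StimulusSet
from lexcat.wordlikeness import distances_to_reference

words_st = st.text(alphabet=string.ascii_uppercase[:6], min_size=1, max_size=8)


class TestEditDistance:
    def test_identity_is_zero(self):
        assert edit_distance("Augen", "Augen") == 0

    def test_single_substitution(self):
        assert edit_distance("Augen", "Augon") == 1

    def test_transposition_variants(self):
        assert edit_distance("AB", "BA", "levenshtein") == 2
        assert edit_distance("AB", "BA", "osa-transposition") == 1

    @settings(max_examples=200, deadline=None)
    @given(words_st, words_st)
    def test_agrees_with_independent_alignment_library(self, a, b):
        assert edit_distance(a, b) == edlib.align(a, b)["editDistance"]

    @settings(max_examples=200, deadline=None)
    @given(words_st, words_st)
    def test_symmetry_and_length_bounds(self, a, b):
        d = edit_distance(a, b)
        assert d == edit_distance(b, a)
        assert abs(len(a) - len(b)) <= d <= max(len(a), len(b))

    @settings(max_examples=200, deadline=None)
    @given(words_st, words_st, words_st)
    def test_triangle_inequality(self, a, b, c):
        assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            edit_distance("", "AB")


class TestOld20:
    def test_constant_distance_reference(self):
        # twenty words, each exactly two substitutions away from the query
        ref_words = [f"AA{c1}{c2}A" for c1 in "BCDE" for c2 in "FGHIK"]
        lex = Lexicon(ref_words, np.ones(20))
        assert old20("AAAAA", lex, exclude_self=False) == 2.0

    def test_matches_full_sort_oracle_on_random_lexica(self):
        rng = np.random.default_rng(99)
        letters = np.array(list("ABCDEFGH"))
        for _ in range(20):
            n = int(rng.integers(25, 120))
            words = list({"".join(rng.choice(letters, size=rng.integers(3, 8)))
                          for _ in range(n)})
            if len(words) < 21:
                continue
            lex = Lexicon(words, np.ones(len(words)))
            query = "".join(rng.choice(letters, size=5))
            oracle = np.mean(
                sorted(edlib.align(query, w)["editDistance"] for w in words)[:20]
            )
            assert old20(query, lex, exclude_self=False) == oracle

    def test_adding_words_never_increases_old20(self):
        lex_small = synth_lexicon(60, seed=4)
        lex_big = Lexicon(
            lex_small.words + ["Xuxux", "Babab"],
            np.concatenate([lex_small.frequencies, [1.0, 1.0]]),
        )
        for q in ["Lagen", "Bodet", "Xuxab"]:
            assert old20(q, lex_big, exclude_self=False) <= old20(
                q, lex_small, exclude_self=False
            )

    def test_exclude_self_removes_own_entry(self):
        lex = synth_lexicon(40, seed=6)
        w = lex.words[0]
        with_self = old20(w, lex, exclude_self=False)
        without = old20(w, lex, exclude_self=True)
        assert with_self < without  # the distance-0 self match deflates the mean

    def test_reference_too_small_names_required_size(self):
        lex = Lexicon(["Abcde"] * 1, np.ones(1))
        with pytest.raises(ValueError, match="20"):
            old20("Query", lex)

    def test_granularity_is_twentieths(self, small_lexicon):
        val = old20("Bagel", small_lexicon)
        assert (val * 20) == pytest.approx(round(val * 20))

    def test_batch_distances_match_scalar_dp(self, small_lexicon):
        d = distances_to_reference("Lumen", small_lexicon)
        for i in [0, 7, 123, 299]:
            assert d[i] == edit_distance("Lumen", small_lexicon.words[i])


class TestColtheartN:
    def test_counts_single_substitution_neighbours(self):
        lex = Lexicon(["CAT", "BIT", "BAN", "BATS", "BAT"], np.ones(5))
        assert coltheart_n("BAT", lex) == 3

    def test_no_matching_length(self):
        lex = Lexicon(["ABCD", "EFGH"], np.ones(2))
        assert coltheart_n("XY", lex) == 0

    def test_self_never_counted(self):
        lex = Lexicon(["BAT"], np.ones(1))
        assert coltheart_n("BAT", lex) == 0


class TestNgramScore:
    def test_summated_token_hand_count(self):
        lex = Lexicon(["ABC", "BCD"], np.array([2.0, 1.0]))
        # "AB" occurs in ABC (freq 2); "BC" in ABC (2) and BCD (1)
        assert ngram_score("ABC", lex, n=2, position="summated") == 5.0

    def test_absent_ngrams_score_zero(self):
        lex = Lexicon(["ABC"], np.array([2.0]))
        assert ngram_score("XYZ", lex, n=2, position="summated") == 0.0

    def test_mean_is_summated_over_positions(self):
        lex = Lexicon(["ABCA", "BCAD"], np.array([3.0, 1.0]))
        s = ngram_score("ABCA", lex, n=2, position="summated")
        m = ngram_score("ABCA", lex, n=2, position="mean")
        assert m == pytest.approx(s / 3)

    def test_initial_and_final_positions(self):
        lex = Lexicon(["ABC", "BCD"], np.array([2.0, 1.0]))
        assert ngram_score("ABC", lex, n=2, position="initial") == 2.0
        assert ngram_score("ABC", lex, n=2, position="final") == 3.0

    def test_ngram_longer_than_string_rejected(self):
        lex = Lexicon(["ABC"], np.ones(1))
        with pytest.raises(ValueError):
            ngram_score("AB", lex, n=3)


class TestBuildTable:
    def test_three_items_three_rows_categories_kept(self, small_lexicon):
        items = StimulusSet(
            [
                StimulusItem(small_lexicon.words[0], "W"),
                StimulusItem("Xyxyx", "PW"),
                StimulusItem("Bcdfg", "CS"),
            ]
        )
        table = build_table(items, small_lexicon, measures=("old20", "coltheart_n"))
        assert len(table) == 3
        assert list(table.data["category"]) == ["W", "PW", "CS"]

    def test_word_frequency_copied_nonwords_zero(self, small_lexicon):
        items = StimulusSet(
            [StimulusItem(small_lexicon.words[2], "W"), StimulusItem("Xyxyx", "PW")]
        )
        table = build_table(items, small_lexicon)
        assert table.data["frequency"].iloc[0] == small_lexicon.frequencies[2]
        assert table.data["frequency"].iloc[1] == 0.0

    def test_duplicate_items_get_identical_rows(self, small_lexicon):
        w = small_lexicon.words[0]
        items = StimulusSet([StimulusItem(w, "W"), StimulusItem(w, "W")])
        table = build_table(items, small_lexicon, measures=("old20",))
        assert table.data["old20"].iloc[0] == table.data["old20"].iloc[1]

    def test_measure_error_names_offending_string(self):
        lex = Lexicon(["Abc", "Abd"], np.ones(2))  # too small for old20
        items = StimulusSet([StimulusItem("Axc", "PW")])
        with pytest.raises(ValueError, match="Axc"):
            build_table(items, lex, measures=("old20",))

    def test_sl_items_carry_nan_measures(self, small_lexicon):
        items = StimulusSet([StimulusItem(None, "SL"), StimulusItem("Xyxyx", "PW")])
        table = build_table(items, small_lexicon, measures=("old20",))
        assert np.isnan(table.data["old20"].iloc[0])
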
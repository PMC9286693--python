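"""Phonological template alignment, 292/300-bit encodings, generation, IO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from noisylex.lexicon import (
    AlignmentError,
    LexiconError,
    Lexeme,
    PHON_BITS,
    SEM_BITS,
    LENGTH_OFFSET,
    STRESS_OFFSET,
    LANGUAGE_OFFSET,
    N_FEATURES,
    align_to_template,
    binarize_embedding,
    encode_phonology,
    generate_synthetic_lexicon,
    load_feature_table,
    load_lexicon,
    save_lexicon,
)
from noisylex.lexicon import format_alignment


class TestAlignment:
    def test_carrot_worked_example(self):
        # kh.{.r.@.t with syllables (kh {)(r @ t): onset/vowel left-alignment
        slots = align_to_template((("kh", "{"), ("r", "@", "t")))
        assert format_alignment(slots) == "kh _ _ { _ r _ _ @ _ t _ _"

    def test_monosyllable_leaves_second_syllable_slots_empty(self):
        slots = align_to_template((("t", "a", "p"),))
        assert slots[8:] == [None] * 5
        assert slots[:8] == ["t", None, None, "a", None, "p", None, None]

    @pytest.mark.parametrize("syllables", [
        (("t", "a", "p"),),
        (("s", "t", "r", "a"), ("d", "a", "k")),
        (("kh", "{"), ("r", "@", "t")),
        (("a",), ("p", "a", "r", "t")),
    ])
    def test_alignment_is_bijection_onto_occupied_slots(self, syllables):
        slots = align_to_template(syllables)
        phonemes = [ph for syl in syllables for ph in syl]
        assert [ph for ph in slots if ph is not None] == phonemes

    def test_overfull_syllable_rejected_with_syllable_identified(self):
        with pytest.raises(AlignmentError, match="syllable 1"):
            align_to_template((("s", "t", "r", "k", "a"),))
        # syllable-2 onset must fit the consonant slots left by syllable 1's coda
        with pytest.raises(AlignmentError, match="syllable 2"):
            align_to_template((("t", "a", "s", "t"), ("s", "t", "r", "a")))

    def test_three_vowels_rejected(self):
        with pytest.raises(AlignmentError):
            align_to_template((("t", "a", "i", "u"),))

    @settings(derandomize=True, max_examples=80)
    @given(st.integers(0, 3), st.integers(1, 2), st.integers(0, 3),
           st.integers(0, 3), st.integers(1, 2), st.integers(0, 3),
           st.booleans())
    def test_alignment_accepts_exactly_the_template_capacities(
            self, on1, nuc1, cod1, on2, nuc2, cod2, disyllabic):
        # any syllable structure within the slot capacities aligns and is a
        # bijection onto occupied slots; anything over capacity is rejected
        cons = ["p", "t", "k", "s", "m", "n"]
        vows = ["a", "e", "i", "o"]
        syl1 = tuple(cons[:on1] + vows[:nuc1] + cons[3:3 + cod1])
        syllables = (syl1,)
        if disyllabic:
            syl2 = tuple(cons[1:1 + on2] + vows[2:2 + nuc2] + cons[2:2 + cod2])
            syllables = (syl1, syl2)
        fits = (not disyllabic and cod1 <= 3) or \
            (disyllabic and cod1 + on2 <= 3 and cod2 <= 3)
        if fits:
            slots = align_to_template(syllables)
            phonemes = [ph for syl in syllables for ph in syl]
            assert [ph for ph in slots if ph is not None] == phonemes
        else:
            with pytest.raises(AlignmentError):
                align_to_template(syllables)


class TestEncoding:
    @pytest.fixture()
    def carrot(self):
        return Lexeme("carrot", "A", (("kh", "{"), ("r", "@", "t")), 1, 0)

    @pytest.fixture()
    def tap(self):
        return Lexeme("tap", "B", (("t", "a", "p"),), 1, 1)

    def test_vector_length_292(self, carrot, tap):
        assert encode_phonology(carrot).shape == (PHON_BITS,) == (292,)
        assert encode_phonology(tap).shape == (292,)

    def test_thermometer_length_bits(self, carrot, tap):
        di = encode_phonology(carrot)
        mono = encode_phonology(tap)
        assert tuple(di[LENGTH_OFFSET:LENGTH_OFFSET + 2]) == (1, 1)
        assert tuple(mono[LENGTH_OFFSET:LENGTH_OFFSET + 2]) == (0, 1)

    def test_stress_one_hot(self, carrot):
        v1 = encode_phonology(carrot)
        assert tuple(v1[STRESS_OFFSET:STRESS_OFFSET + 2]) == (1, 0)
        second = Lexeme("x", "A", carrot.syllables, 2, 9)
        v2 = encode_phonology(second)
        assert tuple(v2[STRESS_OFFSET:STRESS_OFFSET + 2]) == (0, 1)

    def test_prosody_off_zeroes_length_and_stress(self, carrot):
        v = encode_phonology(carrot, use_prosody=False)
        assert not v[LENGTH_OFFSET:LANGUAGE_OFFSET].any()

    def test_language_unit_settings(self, carrot):
        own = encode_phonology(carrot, language_unit="own")
        assert tuple(own[LANGUAGE_OFFSET:]) == (1, 0)  # carrot is language A
        forced = encode_phonology(carrot, language_unit="B")
        assert tuple(forced[LANGUAGE_OFFSET:]) == (0, 1)
        none = encode_phonology(carrot, language_unit=None)
        assert tuple(none[LANGUAGE_OFFSET:]) == (0, 0)

    def test_encoding_deterministic(self, carrot):
        a = encode_phonology(carrot)
        b = encode_phonology(carrot)
        assert (a == b).all()

    def test_shared_onset_words_agree_on_shared_prefix_slots(self):
        a = encode_phonology(Lexeme("tap", "A", (("t", "a", "p"),), 1, 0))
        b = encode_phonology(Lexeme("tat", "A", (("t", "a", "t"),), 1, 1))
        # identical first 5 slots (onset t + vowel a occupy slots 1 and 4)
        k = 5 * N_FEATURES
        assert (a[:k] == b[:k]).all()

    def test_monosyllable_never_sets_second_syllable_feature_bits(self, tap):
        v = encode_phonology(tap)
        assert not v[8 * N_FEATURES: 13 * N_FEATURES].any()

    def test_unknown_phoneme_named_in_error(self):
        with pytest.raises(LexiconError, match="qq"):
            Lexeme("bad", "A", (("qq", "a"),), 1, 0)


class TestFeatureTable:
    def test_rows_are_injective(self):
        table = load_feature_table()
        rows = {tuple(v) for v in table.values()}
        assert len(rows) == len(table)

    def test_rows_have_22_features(self):
        table = load_feature_table()
        assert all(v.shape == (22,) for v in table.values())


class TestBinarizeEmbedding:
    def test_all_zeros_input_gives_all_zero_bits(self):
        assert binarize_embedding(np.zeros(300)).sum() == 0

    def test_strictly_lower_than_threshold(self):
        # boundary value -0.175 itself maps to 0
        vec = np.zeros(300)
        vec[0], vec[1], vec[2] = -0.2, -0.175, 0.3
        bits = binarize_embedding(vec)
        assert tuple(bits[:3]) == (1, 0, 0)

    def test_popcount_matches_elementwise_loop(self, rng):
        vec = rng.normal(0, 1, SEM_BITS)
        bits = binarize_embedding(vec)
        brute = sum(1 for x in vec if x < -0.175)
        assert bits.sum() == brute

    def test_wrong_length_rejected(self):
        with pytest.raises(LexiconError):
            binarize_embedding(np.zeros(299))


class TestSyntheticLexicon:
    def test_default_counts(self):
        lex = generate_synthetic_lexicon(seed=0)
        assert len(lex.lexemes) == 242
        assert lex.counts == {"A": 121, "B": 121}
        di = {lang: sum(lx.n_syllables == 2 for lx in lex.words(lang))
              for lang in "AB"}
        assert di == {"A": 39, "B": 45}

    def test_seeded_determinism(self):
        a = generate_synthetic_lexicon(n_pairs=15, disyllabic_counts={"A": 5, "B": 6}, seed=3)
        b = generate_synthetic_lexicon(n_pairs=15, disyllabic_counts={"A": 5, "B": 6}, seed=3)
        assert a.lexemes == b.lexemes
        assert all((a.sem[p] == b.sem[p]).all() for p in a.sem)

    def test_pairs_share_semantics_and_vector_lengths(self, small_lexicon):
        for lx in small_lexicon.lexemes:
            assert small_lexicon.sem[lx.pair_id].shape == (SEM_BITS,)
            assert encode_phonology(lx).shape == (PHON_BITS,)

    def test_phon_vectors_distinct_within_language(self, small_lexicon):
        for lang in "AB":
            forms = {tuple(encode_phonology(lx, language_unit=None))
                     for lx in small_lexicon.words(lang)}
            assert len(forms) == len(small_lexicon.words(lang))

    def test_popcount_statistics_match_generator_distribution(self):
        # Each bit is marginally Bernoulli(p) by construction (prototype
        # sampling plus expectation-preserving asymmetric flips).  The mean
        # popcount over pairs is dominated by between-cluster variance:
        # Var(mean) ~= Var(prototype popcount) / n_clusters.
        target, n_clusters = 52.7, 8
        lex = generate_synthetic_lexicon(seed=7, sem_ones_target=target,
                                         n_sem_clusters=n_clusters)
        p = target / SEM_BITS
        pops = np.array([lex.sem[pid].sum() for pid in lex.sem])
        sd_mean = np.sqrt(SEM_BITS * p * (1 - p) / n_clusters)
        assert abs(pops.mean() - target) < 3 * sd_mean

    def test_too_few_pairs_rejected(self):
        with pytest.raises(LexiconError):
            generate_synthetic_lexicon(n_pairs=3)


class TestLexiconIO:
    def test_round_trip(self, small_lexicon, tmp_path):
        path = tmp_path / "lex.tsv"
        save_lexicon(small_lexicon, path)
        loaded = load_lexicon(path)
        assert loaded.lexemes == small_lexicon.lexemes
        assert set(loaded.sem) == set(small_lexicon.sem)
        for pid in small_lexicon.sem:
            assert (loaded.sem[pid] == small_lexicon.sem[pid]).all()

    def test_three_syllable_row_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "orthography\tlanguage\tsampa\tstress\tpair_id\n"
            "abc\tA\tt a . p a . k a\t1\t0\n"
            "abc\tB\tt a\t1\t0\n",
            encoding="utf-8")
        with pytest.raises(LexiconError, match=":2"):
            load_lexicon(path)

    def test_incomplete_pair_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "orthography\tlanguage\tsampa\tstress\tpair_id\n"
            "ta\tA\tt a\t1\t0\n",
            encoding="utf-8")
        with pytest.raises(LexiconError, match="pair_id 0"):
            load_lexicon(path)

    def test_export_vectors_matrix(self, small_lexicon, tmp_path):
        from noisylex.lexicon import export_vectors
        path = tmp_path / "phon.tsv"
        export_vectors(small_lexicon, path, kind="phon", language_unit=None)
        lines = path.read_text().splitlines()
        assert len(lines) == len(small_lexicon.lexemes)
        key, *bits = lines[0].split("\t")
        assert key == small_lexicon.lexemes[0].key
        expect = encode_phonology(small_lexicon.lexemes[0], language_unit=None)
        assert [int(b) for b in bits] == expect.tolist()

    def test_apply_real_embeddings_binarizes_rows(self, small_lexicon, tmp_path, rng):
        from noisylex.lexicon import apply_real_embeddings
        path = tmp_path / "emb.tsv"
        reals = {pid: rng.normal(0, 1, SEM_BITS) for pid in small_lexicon.sem}
        path.write_text("\n".join(
            "\t".join([str(pid), *map(str, v)]) for pid, v in reals.items()))
        updated = apply_real_embeddings(small_lexicon, path)
        for pid, v in reals.items():
            assert (updated.sem[pid] == binarize_embedding(v)).all()

    def test_apply_real_embeddings_missing_pair_rejected(self, small_lexicon, tmp_path):
        from noisylex.lexicon import apply_real_embeddings
        path = tmp_path / "emb.tsv"
        path.write_text("0\t" + "\t".join(["0.0"] * SEM_BITS))
        with pytest.raises(LexiconError, match="lacks pairs"):
            apply_real_embeddings(small_lexicon, path)

    def test_duplicate_orthography_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "orthography\tlanguage\tsampa\tstress\tpair_id\n"
            "ta\tA\tt a\t1\t0\n"
            "ta\tB\td a\t1\t0\n"
            "ta\tA\tt u\t1\t1\n"
            "tu\tB\td u\t1\t1\n",
            encoding="utf-8")
        with pytest.raises(LexiconError, match="duplicate"):
            load_lexicon(path)
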
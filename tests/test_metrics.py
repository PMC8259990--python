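"""NLG metric suite against brute-force oracles and printed spot values."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from condlm import metrics as MX
from condlm.metrics import (CiderIdf, bleu_k, bleu_sum, cider, cider_title,
                            evaluate_generation, meteor_lite, rouge_l,
                            word_tokenize)
from condlm.stem import porter_stem

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_bleu_k(hyp, ref, k):
    """Independent n-gram enumerator (positions, clipped counts)."""
    if len(hyp) < k:
        return 0.0
    hgrams = [tuple(hyp[i:i + k]) for i in range(len(hyp) - k + 1)]
    rgrams = [tuple(ref[i:i + k]) for i in range(len(ref) - k + 1)]
    rc = Counter(rgrams)
    matched = sum(min(c, rc[g]) for g, c in Counter(hgrams).items())
    return matched / len(hgrams)


def oracle_lcs(a, b):
    """Exhaustive subsequence enumeration (exponential; tiny inputs only)."""
    best = 0
    for r in range(len(a), best, -1):
        for combo in itertools.combinations(range(len(a)), r):
            sub = [a[i] for i in combo]
            it = iter(b)
            if all(x in it for x in sub):
                return r
    return 0


def random_pair(rng, max_len=8, alphabet=("x", "y", "z")):
    n1, n2 = rng.integers(1, max_len + 1, size=2)
    return ([alphabet[i] for i in rng.integers(0, 3, size=n1)],
            [alphabet[i] for i in rng.integers(0, 3, size=n2)])


class TestBleu:
    def test_identical_texts_score_one(self):
        h = "the cat sat on the mat".split()
        for k in (1, 2, 3, 4):
            assert bleu_k(h, h, k) == 1.0

    def test_disjoint_vocabularies_score_zero(self):
        assert bleu_k("a b".split(), "c d".split(), 1) == 0.0
        assert bleu_sum("a b".split(), "c d".split()) == 0.0

    def test_printed_unigram_example(self):
        assert bleu_k("the cat sat".split(), "the cat ran".split(), 1) \
            == pytest.approx(2 / 3)

    def test_short_hypothesis_scores_zero_at_high_order(self):
        assert bleu_k(["one"], ["one", "two"], 2) == 0.0

    def test_identical_long_text_sums_to_four(self):
        h = "alpha beta gamma delta epsilon".split()
        assert bleu_sum(h, h) == pytest.approx(4.0)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            hyp, ref = random_pair(rng)
            for k in (1, 2, 3):
                assert bleu_k(hyp, ref, k) == pytest.approx(
                    oracle_bleu_k(hyp, ref, k), abs=1e-12)

    def test_multi_reference_clips_by_best_reference(self):
        hyp = "a a b".split()
        refs = ["a c".split(), "a a d".split()]
        # 'a' clips to max(1, 2) = 2; 'b' unmatched -> 2/3
        assert bleu_k(hyp, refs, 1) == pytest.approx(2 / 3)

    @given(st.lists(st.sampled_from("xyz"), min_size=1, max_size=10),
           st.lists(st.sampled_from("xyz"), min_size=1, max_size=10))
    def test_range_invariants(self, hyp, ref):
        for k in (1, 2):
            assert 0.0 <= bleu_k(hyp, ref, k) <= 1.0
        assert 0.0 <= bleu_sum(hyp, ref) <= 4.0


class TestRougeL:
    def test_identical_texts_score_one(self):
        h = "a b c d".split()
        assert rouge_l(h, h) == pytest.approx(1.0)

    def test_disjoint_score_zero(self):
        assert rouge_l("a b".split(), "c d".split()) == 0.0

    def test_printed_formula_example(self):
        # LCS("a b c d", "a b e c f") = 3; p = .75, r = .6, beta = 1.2
        score = rouge_l("a b c d".split(), "a b e c f".split(), beta=1.2)
        assert score == pytest.approx(0.6536, abs=1e-4)

    def test_lcs_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b = random_pair(rng)
            assert MX._lcs_length(a, b) == oracle_lcs(a, b)

    def test_multi_reference_takes_best(self):
        hyp = "a b c".split()
        refs = ["z z".split(), "a b c".split()]
        assert rouge_l(hyp, refs) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def toy():
    docs = ["the gene expresses protein".split(),
            "the cell divides rapidly".split(),
            "protein folding governs function".split()]
    return docs, CiderIdf.from_corpus(docs)


@pytest.fixture(scope="module")
def toy_titled():
    docs = ["gene expression in cancer cells".split(),
            "protein binding controls expression".split(),
            "novel cancer therapy targets".split()]
    return docs, CiderIdf.from_corpus(docs)


class TestCider:
    def test_identical_single_reference_maximal(self, toy):
        docs, idf = toy
        hyp = docs[0]
        # cosine 1 at every order -> score = scale
        assert cider(hyp, [docs[0]], idf) == pytest.approx(10.0)

    def test_disjoint_ngrams_score_zero(self, toy):
        _, idf = toy
        assert cider("x y z".split(), ["the gene".split()], idf) == 0.0

    def test_agrees_with_hand_built_tfidf_cosine(self, toy):
        docs, idf = toy
        hyp = "the gene folding".split()
        ref = docs[0]
        per_order = []
        for n in (1, 2, 3, 4):
            grams = sorted({tuple(d[i:i + n]) for d in docs + [hyp]
                            for i in range(len(d) - n + 1)})
            def vec(doc):
                c = Counter(tuple(doc[i:i + n]) for i in range(len(doc) - n + 1))
                df = Counter()
                for d in docs:
                    df.update({tuple(d[i:i + n]) for i in range(len(d) - n + 1)})
                return np.array([c[g] * math.log(3 / max(df[g], 1))
                                 for g in grams])
            u, v = vec(hyp), vec(ref)
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            per_order.append(float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0)
        assert cider(hyp, [ref], idf) == pytest.approx(
            10 * sum(per_order) / 4, abs=1e-9)

    def test_uniform_idf_reduces_to_count_cosine(self):
        idf = CiderIdf(n_docs=3, df={n: Counter() for n in (1, 2, 3, 4)})
        hyp = "a b".split()
        ref = "a c".split()
        # order 1: cos(<1,1,0>, <1,0,1>) = 0.5; orders 2-4: no overlap
        assert cider(hyp, [ref], idf) == pytest.approx(10 * 0.5 / 4)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            CiderIdf.from_corpus([])


class TestCiderTitle:
    def test_empty_title_equals_plain_cider(self, toy_titled):
        docs, idf = toy_titled
        hyp = "gene expression targets".split()
        assert cider_title(hyp, [docs[0]], [], idf) == pytest.approx(
            cider(hyp, [docs[0]], idf))

    def test_title_only_hypothesis_scores_zero_but_plain_positive(self, toy_titled):
        docs, idf = toy_titled
        title = "gene expression in cancer".split()
        hyp = "gene expression".split()
        assert cider_title(hyp, [docs[0]], title, idf) == 0.0
        assert cider(hyp, [docs[0]], idf) > 0.0

    def test_single_masked_unigram_matches_deleted_coordinate(self, toy_titled):
        docs, idf = toy_titled
        hyp = "gene therapy".split()
        ref = docs[2]
        title = ["therapy"]
        masked = cider_title(hyp, [ref], title, idf)
        # oracle: recompute cosine with the 'therapy' coordinate removed
        def vec(tokens, drop):
            c = Counter(tokens)
            return {g: c[g] * idf.weight((g,)) for g in c if g != drop}
        u, v = vec(hyp, "therapy"), vec(ref, "therapy")
        dot = sum(w * v.get(g, 0.0) for g, w in u.items())
        nu = math.sqrt(sum(w * w for w in u.values()))
        nv = math.sqrt(sum(w * w for w in v.values()))
        expect = 10 * (dot / (nu * nv)) / 4 if nu and nv else 0.0
        assert masked == pytest.approx(expect, abs=1e-9)


class TestMeteorLite:
    def test_no_matches_score_zero(self):
        assert meteor_lite("a b".split(), "c d".split()) == 0.0

    def test_single_identical_token_scores_half(self):
        # m=1, P=R=1 -> F=1; chunks=1 -> penalty 0.5
        assert meteor_lite(["gene"], ["gene"]) == pytest.approx(0.5)

    def test_chunk_count_against_hand_alignment(self):
        # hyp a b c d vs ref a b d c: matches 4, chunks 3 (ab | c | d)
        pairs = MX._align("a b c d".split(), "a b d c".split())
        assert len(pairs) == 4
        assert MX._chunks(pairs) == 3
        score = meteor_lite("a b c d".split(), "a b d c".split())
        assert score == pytest.approx(1.0 * (1 - 0.5 * (3 / 4) ** 3))

    def test_stem_stage_matches_inflected_forms(self):
        score = meteor_lite("running quickly".split(), "run quickly".split())
        assert score > 0.5  # both unigrams align (one exact, one by stem)


class TestPorterStemmer:
    @pytest.mark.parametrize("word,stem", [
        ("caresses", "caress"), ("ponies", "poni"), ("ties", "ti"),
        ("cats", "cat"), ("feed", "feed"), ("agreed", "agre"),
        ("plastered", "plaster"), ("motoring", "motor"),
        ("conflated", "conflat"), ("hopping", "hop"), ("happy", "happi"),
        ("relational", "relat"), ("conditional", "condit"),
    ])
    def test_reference_vocabulary(self, word, stem):
        assert porter_stem(word) == stem


class TestEvaluateGeneration:
    def test_verbatim_generation_perfect_rouge(self):
        ref = "Genes express proteins. Cells divide often."
        report = evaluate_generation(ref, ref, "a title")
        assert report.n_sentences == 2
        assert all(s == pytest.approx(1.0) for s in report.per_sentence["rouge_l"])

    def test_single_sentence_distribution_is_step(self):
        report = evaluate_generation("Genes express proteins.",
                                     "Genes express proteins. Cells divide.",
                                     "title")
        fractions = {f for _, f in report.cumulative["rouge_l"]}
        assert fractions <= {0.0, 1.0}

    def test_cumulative_curves_non_increasing(self):
        report = evaluate_generation(
            "Genes express proteins. Unrelated words here. Cells divide.",
            "Genes express proteins. Cells divide often.", "title")
        for curve in report.cumulative.values():
            fracs = [f for _, f in curve]
            assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_generation_flagged(self):
        report = evaluate_generation("", "A reference sentence.", "title")
        assert report.empty and report.n_sentences == 0

    def test_word_tokenizer_lowercases_and_splits_punctuation(self):
        assert word_tokenize("Gene-X works.") == ["gene", "-", "x", "works", "."]
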
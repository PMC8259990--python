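"""Condition-dependent synthetic corpora with known statistics.

The generator emulates the shape of MEDLINE-style training data — records
with a title, a multi-sentence abstract, a publication year, 1–3 keyword
conditions and word-level POS/dependency/entity annotations — while keeping
every distribution analytically available, so models trained on it can be
checked against ground truth.

The statistical model is deliberately simple: each keyword condition names
a *topic*, a distribution over the word inventory.  A document's word
distribution is ``mixing * mean(selected topics) + (1 - mixing) *
background``; words are drawn i.i.d. from it.  Sentence length is
geometric (after each word the sentence ends with probability
``stop_prob``), which makes the true next-token distribution — including
the sentence terminator — context-free and closed-form.  Per-word labels
are a pure deterministic function of the word string.

This is a statistical stand-in, not a biomedical text simulator: it has no
syntax, no discourse structure and no correlation between adjacent words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from hashlib import blake2b

import numpy as np

from . import labels as L
from .corpus import MedlineRecord, WordAnnotation

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"


def _pseudo_word(i: int, length: int = 3) -> str:
    """Readable deterministic pseudo-word ('bafu', 'cegi', ...)."""
    h = blake2b(str(i).encode(), digest_size=length * 2, key=b"words").digest()
    out = []
    for j in range(length):
        out.append(_CONSONANTS[h[2 * j] % len(_CONSONANTS)])
        out.append(_VOWELS[h[2 * j + 1] % len(_VOWELS)])
    return "".join(out)


def word_labels(word: str) -> tuple[str, str, str]:
    """Deterministic (POS, dependency, entity) labels for a word.

    A keyed hash of the word picks from a few content POS tags and
    dependency relations; roughly a third of words land in one of the 14
    typed entity classes, the rest are "not an entity".
    """
    h = blake2b(word.encode(), digest_size=8, key=b"labels").digest()
    pos = ("NOUN", "VERB", "ADJ", "ADV", "PROPN")[h[0] % 5]
    dep = ("nsubj", "obj", "amod", "advmod", "nmod", "compound", "conj")[h[1] % 7]
    entity = L.ENTITY_CLASSES[h[2] % 14] if h[3] % 3 == 0 else L.NOT_ENTITY
    return pos, dep, entity


@dataclass
class SyntheticGrammar:
    """A condition-dependent unigram grammar over a finite word inventory."""

    words: list[str]
    topics: dict[str, np.ndarray]          # keyword -> distribution over words
    background: np.ndarray                 # distribution over words
    mixing: float = 0.8                    # topic weight vs background
    stop_prob: float = 0.15                # geometric sentence-length parameter
    punctuation: str = "."
    year_range: tuple[int, int] = (1980, 2020)
    min_keywords: int = 1
    max_keywords: int = 3
    abstract_sentences: tuple[int, int] = (2, 6)
    _word_index: dict[str, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        for name, dist in list(self.topics.items()):
            dist = np.asarray(dist, dtype=float)
            if abs(dist.sum() - 1.0) > 1e-9:
                raise ValueError(f"topic {name!r} distribution does not sum to 1")
            self.topics[name] = dist
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background distribution does not sum to 1")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")
        self._word_index = {w: i for i, w in enumerate(self.words)}

    @property
    def keywords(self) -> list[str]:
        return sorted(self.topics)

    # -- exact distributions -------------------------------------------------
    def word_distribution(self, conditions) -> np.ndarray:
        """Exact word distribution under a condition set (empty set:
        background only)."""
        conditions = list(conditions)
        for c in conditions:
            if c not in self.topics:
                raise ValueError(f"unknown condition keyword {c!r}")
        if not conditions:
            return self.background.copy()
        topic = np.mean([self.topics[c] for c in conditions], axis=0)
        return self.mixing * topic + (1.0 - self.mixing) * self.background

    def token_distribution(self, conditions) -> np.ndarray:
        """Next-token distribution over ``words + [punctuation]``, given
        that the previous token was a word.

        Geometric sentence lengths make this context-free within a
        sentence: after any word the next token is the terminator with
        probability ``stop_prob``, otherwise a word from the conditional
        word distribution.  (After a terminator a word follows surely.)
        """
        w = self.word_distribution(conditions)
        return np.concatenate([(1.0 - self.stop_prob) * w, [self.stop_prob]])

    def marginal_token_distribution(self) -> np.ndarray:
        """Stationary token frequencies marginalized over documents.

        Keyword subsets are drawn symmetrically, so the expected topic
        mixture is the mean over all topics; a sentence of geometric length
        L (mean 1/stop_prob) contributes one terminator per L words, so the
        terminator's stationary mass is ``stop_prob / (1 + stop_prob)``.
        """
        mean_topic = np.mean(list(self.topics.values()), axis=0)
        w = self.mixing * mean_topic + (1.0 - self.mixing) * self.background
        q = self.stop_prob
        return np.concatenate([w / (1.0 + q), [q / (1.0 + q)]])

    def conditional_entropy(self, conditions) -> float:
        """Shannon entropy (nats) of the next-token distribution."""
        p = self.token_distribution(conditions)
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    def topic_support(self, keyword: str) -> set[str]:
        dist = self.topics[keyword]
        return {self.words[i] for i in np.flatnonzero(dist > 0)}


def default_grammar(n_words: int = 200, n_topics: int = 4,
                    mixing: float = 0.8, disjoint: bool = True,
                    stop_prob: float = 0.15, seed: int = 0,
                    ) -> SyntheticGrammar:
    """Build a grammar with Zipf-weighted background and per-topic supports.

    ``disjoint=True`` gives each topic an exclusive word slice (the sharp
    setting used for conditional-control checks); otherwise topic supports
    are random subsets that may overlap.
    """
    rng = np.random.default_rng(seed)
    words: list[str] = []
    seen: set[str] = set()
    i = 0
    while len(words) < n_words:       # skip rare hash collisions
        w = _pseudo_word(i)
        i += 1
        if w not in seen:
            seen.add(w)
            words.append(w)
    ranks = np.arange(1, n_words + 1, dtype=float)
    background = (1.0 / ranks) / (1.0 / ranks).sum()

    topics: dict[str, np.ndarray] = {}
    per = n_words // n_topics
    for t in range(n_topics):
        dist = np.zeros(n_words)
        if disjoint:
            support = np.arange(t * per, (t + 1) * per)
        else:
            support = rng.choice(n_words, size=per, replace=False)
        dist[support] = rng.dirichlet(np.ones(len(support)) * 2.0)
        topics[f"topic_{chr(97 + t)}"] = dist
    return SyntheticGrammar(words=words, topics=topics, background=background,
                            mixing=mixing, stop_prob=stop_prob)


# ---------------------------------------------------------------------------
# corpus sampling
# ---------------------------------------------------------------------------

def _sample_sentence(grammar: SyntheticGrammar, dist: np.ndarray,
                     rng: np.random.Generator) -> list[str]:
    words = []
    while True:
        words.append(grammar.words[rng.choice(len(dist), p=dist)])
        if rng.random() < grammar.stop_prob:
            return words


def _render(sentences: list[list[str]], grammar: SyntheticGrammar,
            offset: int) -> tuple[str, list[WordAnnotation]]:
    """Join word lists into text ('wa ke lo. ...') with per-word spans."""
    parts: list[str] = []
    anns: list[WordAnnotation] = []
    pos_cursor = offset
    for si, words in enumerate(sentences):
        if si > 0:
            parts.append(" ")
            pos_cursor += 1
        for wi, w in enumerate(words):
            if wi > 0:
                parts.append(" ")
                pos_cursor += 1
            pos, dep, ent = word_labels(w)
            anns.append(WordAnnotation(pos_cursor, pos_cursor + len(w),
                                       pos, dep, ent))
            parts.append(w)
            pos_cursor += len(w)
        anns.append(WordAnnotation(pos_cursor, pos_cursor + 1,
                                   "PUNCT", "punct", L.NOT_ENTITY))
        parts.append(grammar.punctuation)
        pos_cursor += 1
    return "".join(parts), anns


def sample_corpus(grammar: SyntheticGrammar, n_docs: int,
                  rng: np.random.Generator | int | None = None,
                  ) -> list[MedlineRecord]:
    """Draw ``n_docs`` annotated records from the grammar.

    Each record selects 1–3 keyword conditions uniformly without
    replacement, a year uniform over the grammar's range, a one-sentence
    title and a 2–6 sentence abstract, all words i.i.d. from the
    condition's mixture distribution.  Byte-identical for a fixed seed.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    keywords = grammar.keywords
    records: list[MedlineRecord] = []
    for i in range(n_docs):
        k = int(rng.integers(grammar.min_keywords,
                             min(grammar.max_keywords, len(keywords)) + 1))
        chosen = sorted(rng.choice(len(keywords), size=k, replace=False))
        conds = [keywords[j] for j in chosen]
        dist = grammar.word_distribution(conds)
        year = int(rng.integers(grammar.year_range[0], grammar.year_range[1]))
        title_words = [_sample_sentence(grammar, dist, rng)]
        lo, hi = grammar.abstract_sentences
        n_sent = int(rng.integers(lo, hi + 1))
        abstract_sents = [_sample_sentence(grammar, dist, rng)
                          for _ in range(n_sent)]
        title, title_anns = _render(title_words, grammar, offset=0)
        abstract, abs_anns = _render(abstract_sents, grammar,
                                     offset=len(title) + 1)
        records.append(MedlineRecord(
            id=f"synth-{i:06d}", title=title, abstract=abstract, year=year,
            keywords=set(conds), language="eng",
            annotations=title_anns + abs_anns,
        ))
    return records
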
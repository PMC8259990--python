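"""N-gram NLG evaluation: Bleu-k, summed Bleu, ROUGE-L, CIDEr variants,
a METEOR-style score, and the sentence-wise multi-reference protocol.

Two of these differ deliberately from the scorers in common NLP toolkits,
matching the definitions this package evaluates with:

* ``bleu_k`` is a *per-order* clipped precision with **no** brevity penalty
  and no geometric mean: the count of hypothesis k-grams that also appear
  in the reference (clipped by the reference count; max over references),
  divided by the number of k-gram positions in the hypothesis.
  ``bleu_sum`` simply adds the orders 1–4, so it ranges over [0, 4].
* ``cider_title`` is CIDEr with the TF-IDF weight of every n-gram that
  occurs in the title forced to zero, in both hypothesis and reference
  vectors — a sentence made solely of title n-grams scores exactly 0.
  It quantifies non-trivial generation beyond parroting the prompt.

ROUGE-L is the longest-common-subsequence F-measure with beta = 1.2.
CIDEr follows the reference convention: per order n = 1..4, the cosine
similarity between TF-IDF n-gram vectors of hypothesis and reference,
averaged over references, then averaged over orders and scaled by 10.
``meteor_lite`` is the classic METEOR harmonic mean with exact and
Porter-stem matching stages (no synonym stage, which needs a lexical
database) and the standard chunk-based fragmentation penalty.

Word tokenization here (lowercase, split on word/punctuation boundaries)
is independent of the subword tokenizer used for modeling.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field

from .corpus import split_sentences
from .stem import porter_stem

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")

Tokens = list[str]


def word_tokenize(text: str) -> Tokens:
    """Lowercased word/punctuation tokens for metric computation."""
    return _TOKEN_RE.findall(text.lower())


def _as_refs(ref) -> list[Tokens]:
    """Accept a single token sequence or a list of them."""
    if ref and isinstance(ref[0], str):
        return [list(ref)]
    return [list(r) for r in ref]


def _ngrams(tokens: Tokens, k: int) -> Counter:
    return Counter(tuple(tokens[i:i + k]) for i in range(len(tokens) - k + 1))


# ---------------------------------------------------------------------------
# Bleu
# ---------------------------------------------------------------------------

def bleu_k(hyp: Tokens, ref, k: int, distinct: bool = False) -> float:
    """Order-k clipped n-gram precision (no brevity penalty).

    ``distinct=True`` divides by the number of *distinct* hypothesis
    k-grams instead of the number of k-gram positions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not hyp:
        logger.warning("bleu_k: empty hypothesis scores 0")
        return 0.0
    if len(hyp) < k:
        return 0.0
    refs = _as_refs(ref)
    hc = _ngrams(hyp, k)
    matched = 0
    for gram, n in hc.items():
        clip = max(_ngrams(r, k).get(gram, 0) for r in refs)
        matched += min(n, clip)
    denom = len(hc) if distinct else (len(hyp) - k + 1)
    return matched / denom


def bleu_sum(hyp: Tokens, ref) -> float:
    """Summed Bleu over orders 1–4; ranges over [0, 4]."""
    return sum(bleu_k(hyp, ref, k) for k in (1, 2, 3, 4))


# ---------------------------------------------------------------------------
# ROUGE-L
# ---------------------------------------------------------------------------

def _lcs_length(a: Tokens, b: Tokens) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y
                       else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_l(hyp: Tokens, ref, beta: float = 1.2) -> float:
    """LCS-based F-measure; with multiple references, the best is taken."""
    if not hyp:
        return 0.0
    refs = _as_refs(ref)
    if not any(refs):
        raise ValueError("ROUGE-L requires a non-empty reference")
    best = 0.0
    for r in refs:
        s = _lcs_length(hyp, r)
        if s == 0:
            continue
        p = s / len(hyp)
        rr = s / len(r)
        best = max(best, (1 + beta ** 2) * p * rr / (rr + beta ** 2 * p))
    return best


# ---------------------------------------------------------------------------
# CIDEr
# ---------------------------------------------------------------------------

@dataclass
class CiderIdf:
    """Per-order document frequencies over a reference corpus."""

    n_docs: int
    df: dict[int, Counter] = field(repr=False)
    orders: tuple[int, ...] = (1, 2, 3, 4)

    @classmethod
    def from_corpus(cls, documents: list[Tokens],
                    orders: tuple[int, ...] = (1, 2, 3, 4)) -> "CiderIdf":
        if not documents:
            raise ValueError("CIDEr idf statistics need a non-empty corpus")
        df = {n: Counter() for n in orders}
        for doc in documents:
            for n in orders:
                df[n].update(set(_ngrams(doc, n)))
        return cls(n_docs=len(documents), df=df, orders=orders)

    def weight(self, gram: tuple[str, ...]) -> float:
        n = len(gram)
        return math.log(self.n_docs / max(self.df[n].get(gram, 0), 1))


def _tfidf_vector(tokens: Tokens, n: int, idf: CiderIdf,
                  masked: set | None = None) -> dict:
    vec = {}
    for gram, c in _ngrams(tokens, n).items():
        if masked and gram in masked:
            continue
        w = c * idf.weight(gram)
        if w != 0.0:
            vec[gram] = w
    return vec


def _cosine(u: dict, v: dict) -> float:
    if not u or not v:
        return 0.0
    dot = sum(w * v[g] for g, w in u.items() if g in v)
    nu = math.sqrt(sum(w * w for w in u.values()))
    nv = math.sqrt(sum(w * w for w in v.values()))
    return dot / (nu * nv) if nu > 0 and nv > 0 else 0.0


def cider(hyp: Tokens, refs, idf: CiderIdf, title: Tokens | None = None,
          scale: float = 10.0) -> float:
    """TF-IDF n-gram consensus score.

    Per order, the cosine similarity between hypothesis and reference
    TF-IDF vectors is averaged over references; the final score is the mean
    over orders times ``scale``.  When ``title`` is given, every n-gram
    occurring in it carries zero weight on both sides (the title-masked
    variant).
    """
    refs = _as_refs(refs)
    if not refs:
        raise ValueError("CIDEr requires at least one reference")
    per_order = []
    for n in idf.orders:
        masked = set(_ngrams(title, n)) if title is not None else None
        hv = _tfidf_vector(hyp, n, idf, masked)
        sims = [_cosine(hv, _tfidf_vector(r, n, idf, masked)) for r in refs]
        per_order.append(sum(sims) / len(sims))
    return scale * sum(per_order) / len(per_order)


def cider_title(hyp: Tokens, refs, title: Tokens, idf: CiderIdf,
                scale: float = 10.0) -> float:
    """CIDEr with every title n-gram's weight forced to zero."""
    return cider(hyp, refs, idf, title=title, scale=scale)


# ---------------------------------------------------------------------------
# METEOR (exact + stem stages)
# ---------------------------------------------------------------------------

def _align(hyp: Tokens, ref: Tokens) -> list[tuple[int, int]]:
    """Unigram alignment: exact matches first, then stem matches."""
    pairs: list[tuple[int, int]] = []
    used_h: set[int] = set()
    used_r: set[int] = set()
    for key in (lambda w: w, porter_stem):
        ref_slots: dict[str, list[int]] = {}
        for j, w in enumerate(ref):
            if j not in used_r:
                ref_slots.setdefault(key(w), []).append(j)
        for i, w in enumerate(hyp):
            if i in used_h:
                continue
            slots = ref_slots.get(key(w))
            if slots:
                j = slots.pop(0)
                pairs.append((i, j))
                used_h.add(i)
                used_r.add(j)
    return sorted(pairs)


def _chunks(pairs: list[tuple[int, int]]) -> int:
    chunks = 0
    prev = None
    for i, j in pairs:
        if prev is None or i != prev[0] + 1 or j != prev[1] + 1:
            chunks += 1
        prev = (i, j)
    return chunks


def meteor_lite(hyp: Tokens, ref) -> float:
    """METEOR-style score with exact and Porter-stem matching stages.

    ``F = 10PR / (R + 9P)`` over aligned unigrams, discounted by the
    fragmentation penalty ``0.5 * (chunks / matches)^3``; with several
    references the best-scoring one wins.
    """
    if not hyp:
        return 0.0
    best = 0.0
    for r in _as_refs(ref):
        if not r:
            continue
        pairs = _align(hyp, r)
        m = len(pairs)
        if m == 0:
            continue
        p = m / len(hyp)
        rec = m / len(r)
        f = 10 * p * rec / (rec + 9 * p)
        penalty = 0.5 * (_chunks(pairs) / m) ** 3
        best = max(best, f * (1.0 - penalty))
    return best


# ---------------------------------------------------------------------------
# sentence-wise evaluation protocol
# ---------------------------------------------------------------------------

METRIC_NAMES = ("bleu_1", "bleu_sum", "rouge_l", "cider", "cider_title",
                "meteor")


@dataclass
class MetricReport:
    """Per-sentence scores, aggregate means, and cumulative distributions.

    ``cumulative[name]`` is a list of ``(threshold, fraction of sentences
    scoring >= threshold)`` pairs, non-increasing in the threshold.
    """

    per_sentence: dict[str, list[float]]
    mean: dict[str, float]
    cumulative: dict[str, list[tuple[float, float]]]
    n_sentences: int
    empty: bool = False


def _cumulative(scores: list[float], n_points: int = 21,
                ) -> list[tuple[float, float]]:
    if not scores:
        return []
    top = max(max(scores), 1e-12)
    out = []
    for i in range(n_points):
        t = top * i / (n_points - 1)
        out.append((t, sum(s >= t for s in scores) / len(scores)))
    return out


def evaluate_generation(generated: str, reference: str, title: str,
                        idf: CiderIdf | None = None) -> MetricReport:
    """Score a generated abstract sentence-by-sentence.

    Each generated sentence is compared against the full set of reference
    sentences (the human-written abstract) for every metric.  ``idf``
    defaults to statistics over the reference sentences; pass corpus-level
    statistics when scoring many documents.
    """
    hyp_sents = [word_tokenize(s) for s in split_sentences(generated.strip())]
    hyp_sents = [s for s in hyp_sents if s]
    ref_sents = [word_tokenize(s) for s in split_sentences(reference.strip())]
    ref_sents = [s for s in ref_sents if s]
    if not ref_sents:
        raise ValueError("reference abstract has no sentences")
    title_tokens = word_tokenize(title)
    if idf is None:
        idf = CiderIdf.from_corpus(ref_sents)

    if not hyp_sents:
        logger.warning("evaluate_generation: empty generation")
        return MetricReport(per_sentence={m: [] for m in METRIC_NAMES},
                            mean={m: 0.0 for m in METRIC_NAMES},
                            cumulative={m: [] for m in METRIC_NAMES},
                            n_sentences=0, empty=True)

    per: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for sent in hyp_sents:
        per["bleu_1"].append(bleu_k(sent, ref_sents, 1))
        per["bleu_sum"].append(bleu_sum(sent, ref_sents))
        per["rouge_l"].append(rouge_l(sent, ref_sents))
        per["cider"].append(cider(sent, ref_sents, idf))
        per["cider_title"].append(cider_title(sent, ref_sents, title_tokens, idf))
        per["meteor"].append(meteor_lite(sent, ref_sents))
    return MetricReport(
        per_sentence=per,
        mean={m: sum(v) / len(v) for m, v in per.items()},
        cumulative={m: _cumulative(v) for m, v in per.items()},
        n_sentences=len(hyp_sents),
    )
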
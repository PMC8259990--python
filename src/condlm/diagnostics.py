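"""Ground-truth diagnostics for models trained on synthetic grammars.

A grammar from :mod:`condlm.synthetic` has a closed-form next-token
distribution; a trained model has a next-token distribution over subword
pieces.  To compare the two, subword pieces are mapped back to grammar
words (a piece equal to a word, with or without its leading space, belongs
to that word; the sentence terminator maps to a punctuation bucket;
everything else — characters, fragments, specials — falls into a residual
bucket that counts fully against the distance).  The comparison is the
total-variation distance between the model's predicted distribution,
averaged over a handful of in-distribution contexts, and the grammar's
exact conditional.
"""

from __future__ import annotations

import numpy as np

from . import model as M
from .corpus import ConditionIndex
from .subtoken import SubwordVocab, segment
from .synthetic import SyntheticGrammar


def piece_word_map(vocab: SubwordVocab, grammar: SyntheticGrammar,
                   ) -> dict[int, str]:
    """Map token ids to grammar words (or the punctuation mark)."""
    out: dict[int, str] = {}
    for tid in range(4, vocab.size):
        piece = vocab.piece(tid)
        bare = piece[1:] if piece.startswith(" ") else piece
        if bare in grammar._word_index:
            out[tid] = bare
        elif bare == grammar.punctuation:
            out[tid] = grammar.punctuation
    return out


def model_token_distribution(params: M.ModelParams, vocab: SubwordVocab,
                             cond_index: ConditionIndex,
                             grammar: SyntheticGrammar, keyword: str,
                             year: int = 2000, n_contexts: int = 10,
                             context_words: int = 6,
                             seed: int = 99) -> np.ndarray:
    """Model next-token distribution under one keyword condition.

    Averaged over ``n_contexts`` mid-sentence contexts drawn from the
    grammar's own conditional, and aggregated from pieces to the grammar's
    word inventory.  The returned vector is indexed ``words +
    [punctuation, other]`` and sums to 1.
    """
    word_map = piece_word_map(vocab, grammar)
    n_words = len(grammar.words)
    acc = np.zeros(n_words + 2)
    rng = np.random.default_rng(seed)
    dist = grammar.word_distribution([keyword])
    cond = [cond_index.year_index(year)]
    kw_idx = cond_index.keyword_index(keyword)
    if kw_idx is None:
        raise ValueError(f"keyword {keyword!r} not in the condition index")
    cond.append(kw_idx)
    cond_arr = np.asarray([cond], dtype=np.int64)
    for _ in range(n_contexts):
        words = [grammar.words[rng.choice(n_words, p=dist)]
                 for _ in range(context_words)]
        ctx = [vocab.soa_id] + segment(" ".join(words), vocab)
        batch = M.Batch(
            token_ids=np.asarray([ctx], dtype=np.int64),
            token_mask=np.ones((1, len(ctx)), dtype=bool),
            cond_ids=cond_arr,
            cond_mask=np.ones_like(cond_arr, dtype=bool),
        )
        out = M.forward(batch, params, mode="eval")
        z = out.token_logits.data[0, -1]
        p = np.exp(z - z.max())
        p /= p.sum()
        for tid, pi in enumerate(p):
            w = word_map.get(tid)
            if w == grammar.punctuation:
                acc[n_words] += pi
            elif w is not None:
                acc[grammar._word_index[w]] += pi
            else:
                acc[n_words + 1] += pi
    return acc / n_contexts


def conditional_control_tv(params: M.ModelParams, vocab: SubwordVocab,
                           cond_index: ConditionIndex,
                           grammar: SyntheticGrammar, keyword: str,
                           **kwargs) -> float:
    """Total-variation distance between the model's conditional next-token
    distribution and the grammar's exact one (residual mass counts)."""
    model_p = model_token_distribution(params, vocab, cond_index, grammar,
                                       keyword, **kwargs)
    truth = np.concatenate([grammar.token_distribution([keyword]), [0.0]])
    return float(0.5 * np.abs(model_p - truth).sum())


def topic_word_counts(text: str, grammar: SyntheticGrammar,
                      keyword: str) -> int:
    """Number of tokens in ``text`` that belong to a keyword's topic support."""
    support = grammar.topic_support(keyword)
    tokens = text.replace(grammar.punctuation, " ").split()
    return sum(t in support for t in tokens)
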
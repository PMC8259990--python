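"""Train a unigram subword vocabulary and segment text with it.

Builds a small corpus from the synthetic grammar, trains a 120-piece
vocabulary, and shows both deterministic (Viterbi) and probabilistic
segmentation of one sentence.
"""

from condlm import build_vocab, detokenize, sample_corpus, segment
from condlm.synthetic import default_grammar

grammar = default_grammar(n_words=50, n_topics=2, seed=1)
records = sample_corpus(grammar, 200, rng=1)
vocab = build_vocab([r.text for r in records], size=120, seed=13)

text = records[0].title
print("text:      ", text)
ids = segment(text, vocab)
print("viterbi:   ", [vocab.piece(t) for t in ids])
for s in range(3):
    alt = segment(text, vocab, mode="sample", alpha=5.0, seed=s)
    print(f"sample {s}:  ", [vocab.piece(t) for t in alt])
print("round trip:", detokenize(ids, vocab) == text.lower())
# The Viterbi line is the single highest-probability tiling of the sentence
# into vocabulary pieces.  The sampled lines draw alternative tilings with
# probability proportional to exp(score/alpha): at alpha=1 the whole-word
# tiling dominates so strongly that samples rarely differ; the flattened
# alpha=5 draws expose the competing character-level paths used for subword
# regularization during training.
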
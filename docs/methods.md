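# Methods

This note records the modeling choices, defaults and numerical decisions
behind `condlm`, and what the synthetic-data experiments do and do not
establish.

## Model

The network is an encoder–decoder transformer specialised for conditional
left-to-right language modeling. The encoder input E₀ is the set of
condition embeddings (one per keyword, one for the publication year) with
**no positional encoding**: conditions are a set, and permutation
invariance of all outputs is enforced by test rather than assumed. The
decoder input D₀ is the token embedding plus the sinusoidal positional
code PE(pos, 2i) = sin(pos/10000^(2i/d)), PE(pos, 2i+1) = cos(·). Each
decoder block applies causally masked self-attention, then attention onto
the encoder output, then a ReLU feed-forward expansion; every sublayer is
post-normed, LayerNorm(f(x)+x). Post-norm is a deliberate departure from
the pre-norm layout common in GPT-style models: the block equations are
implemented exactly as written above, and the tiny configurations used
here train stably with warmup.

Four linear heads map final decoder states to logits for the next subword
token and the next token's POS tag (17 universal tags), dependency
relation (19 UD-style relations) and entity class (14 biomedical entity
types + "not an entity" = 15). Head matrices are separate parameters,
untied from the input embedding table, and the condition embedding table
is separate from the token table.

**Loss.** Each head contributes the mean cross-entropy −log softmax(zᵢ)[ℓᵢ]
over non-padding positions; the total is the plain sum of the four
components. Averaging (rather than summing) over positions keeps the loss
scale independent of window length and batch size. All label tracks are
shifted by one position (teacher forcing): position i, which sees tokens
≤ i, predicts token i+1 and that token's labels.

**Defaults.** The full-scale configuration is GPT-2-medium-like: embedding
1024, 16 heads, 2 encoder and 16 decoder blocks, feed-forward 3072,
dropout 0.1 between sublayers (applied to each sublayer output before its
residual add — the conventional site), maximum sequence 128, 16 000-piece
token vocabulary. Initialization is scaled normal (σ = 0.02) for matrices,
ones/zeros for normalization gains/offsets. Desk-scale runs shrink to
embedding 64, 2 heads, 1+2 blocks, feed-forward 128.

**Masking details.** Attention masks are boolean with masked keys receiving
exactly zero weight (additive −1e30 before the softmax, which underflows
to zero); a query row with every key masked is treated as a contract
violation and raises. Padded condition slots are masked out of encoder
self-attention and of cross-attention; padded token positions are masked
out of the loss and, as keys, out of decoder self-attention.

## Engine

No deep-learning framework is used: `condlm.autograd` is a ~300-line
reverse-mode autodiff engine over float64 numpy arrays providing exactly
the operators the model needs (batched matmul, broadcast add/mul, ReLU,
log-softmax with additive masks, layer normalization, embedding
lookup/scatter, shape ops). Float64 keeps finite-difference gradient
checks tight (the test suite verifies analytic gradients to ≲1e-3 relative
on a toy configuration, and observed agreement is ~1e-9 absolute).

## Optimization

Adam is the desk-scale default; LAMB (Adam update rescaled per parameter
by ‖θ‖/‖update‖) is implemented and selectable, since its benefit appears
at effective batch sizes in the hundreds, far above desk scale. The
learning rate warms up linearly (default 500 steps) to the base rate
(default 1e-3; desk studies use 3e-3) and stays flat — no decay is
applied. Effective batch sizes beyond the device batch are obtained by
gradient accumulation; note the per-window (rather than per-position)
weighting makes accumulated and monolithic batches agree only up to
window-length variation.

"Epoch" for checkpointing means one pass over 5% of the corpus
(configurable). Every document view draws a fresh window uniformly over
sentence starts. Checkpoints store parameters, optimizer moments, the
generator state and the corpus cursor, so a resumed run reproduces the
uninterrupted loss trajectory exactly on one machine.

## Data preparation

Records are kept if their language tag is English and the abstract
contains at least one sentence; keyword-less records are retained (their
condition is the year alone, so every window has ≥ 1 condition). The
train/test split orders record ids by a seeded keyed hash and cuts at
round(ratio·n): deterministic, exhaustive, and exact to one record — a
per-record independent coin flip was rejected because its ±1.4% fraction
noise at n = 1000 violates the documented 1% accuracy contract.

Keywords are opaque strings, trimmed and lowercased; those occurring fewer
than 10 times in the training partition are pruned. Year indexing is
half-open [min_year, cutoff): with the earliest year 1790 and cutoff 2020
this yields 230 indices, which is the convention that reproduces the
standard embedding count for that range; years outside the range clamp to
the nearest end.

The document text is `title + " " + abstract`, wrapped in start/end
specials, with the title counted as the first sentence. This puts the
title at the sequence head, making training windows and generation prompts
(start token + segmented title) consistent. Sentence boundaries come from
a deterministic rule-based splitter (terminator + whitespace +
letter/digit lookahead); the splitter is a pluggable seam for a real
annotation pipeline.

**Label alignment.** Word-level annotations (span, POS, dependency,
entity) are projected onto subwords: a subword inherits the labels of the
word containing its first non-whitespace character (word-boundary pieces
carry their preceding space); subwords outside any span get fallback
labels (POS "X", dependency "dep", entity "not an entity"). Overlapping
annotation spans are a provider-contract violation and raise.

## Subword tokenizer

The vocabulary trainer is self-contained: candidates are all observed
characters plus frequent word-boundary-aware substrings (words keep their
leading space, as in sentencepiece's word-marker convention); a few rounds
of Viterbi EM re-estimate unigram log-probabilities and retire unused
pieces; the final inventory is pruned to the exact requested size with
character coverage forced, so any string over the training alphabet stays
segmentable. Characters never seen in training map to the unknown id
rather than raising — real bibliographic text contains rare glyphs.
Segmentation is lattice Viterbi; sampling mode draws a path with
probability ∝ exp(score/α) via forward-filtering backward-sampling, and
α → 0 recovers Viterbi. Training uses Viterbi segmentation by default;
sampled segmentation is available but off, since its regularization
benefit is not measurable at desk scale. The vocabulary serializes as
TSV (piece, log-probability; specials first in fixed order pad, unk,
start, end) with backslash escaping, round-tripping bit-exactly.

## Generation

Ancestral sampling with temperature, optional top-k and nucleus (top-p)
truncation; temperature 0 is greedy argmax. The prompt is the start token
plus the segmented title; generation stops at the end-of-abstract token or
a length cap. When prompt+generation exceeds the model's maximum sequence
length, a sliding window keeps the most recent tokens as context. The
padding id (and a second start token) are masked out of every sampling
step. Unknown condition keywords are dropped with a warning — they
correspond to keywords pruned from the index.

## Evaluation metrics

Bleu-k here is a *per-order clipped precision*: matched k-gram count
(clipped by the reference count, max over references) divided by the
number of k-gram positions in the hypothesis — no brevity penalty and no
geometric mean, and the summed variant simply adds orders 1–4 (range
[0, 4]). Where the divisor could be read as the count of *distinct*
hypothesis k-grams instead of positions, the position reading is the
default (it makes identical texts score exactly 1 even with repeated
grams); the distinct reading is available behind a flag. These definitions
intentionally differ from mainstream Bleu scorers, which is why the test
suite cross-checks against brute-force enumeration oracles rather than a
third-party scorer.

ROUGE-L is the LCS F-measure with β = 1.2. CIDEr follows the original
convention: orders 1–4 weighted uniformly, TF-IDF vectors with
idf = log(N/df) over the reference corpus (the evaluation set's reference
abstracts by default), cosine per order averaged over references, final
score ×10. CIDEr-Title zeroes the weight of every n-gram occurring in the
title in both hypothesis and reference vectors, so a sentence composed
entirely of title n-grams scores exactly 0. The METEOR-style score uses
exact matching then Porter-stem matching (no synonym stage — that needs a
lexical database, hence the name `meteor_lite`), F = 10PR/(R+9P), and the
chunk penalty 0.5·(chunks/matches)³.

The protocol is sentence-wise and multi-reference: each generated sentence
is scored against the full set of reference-abstract sentences; reports
carry per-sentence scores, means, and cumulative distributions (fraction
of sentences scoring ≥ threshold). Metric tokenization (lowercase,
word/punctuation split) is independent of the subword tokenizer.

## Synthetic grammar

The generator emulates the *shape* of MEDLINE training data — title,
multi-sentence abstract, year, 1–3 keyword conditions, word-level
annotations — with fully analytic statistics. Each keyword names a topic
distribution over a finite word inventory; a document's words are i.i.d.
from mixing·mean(selected topics) + (1−mixing)·background. Sentence
lengths are geometric (stop probability 0.15 by default, mean ≈ 6.7
words), chosen so the next-token distribution *given the previous token
was a word* is context-free and closed-form; the stationary terminator
frequency is q/(1+q). Keyword subsets are drawn symmetrically, so the
marginal word distribution is the mean over topics — also closed-form.
Labels are a pure keyed-hash function of the word string. Defaults: 200
words, 4 topics, mixing 0.8; control studies use 2 topics with disjoint
supports and mixing 1.0 for a sharp signal.

What passing tests on this grammar shows: the conditioning pathway,
teacher forcing, masking, alignment and optimization are correct, and the
model family can recover a known conditional distribution. What it does
not show: anything about syntax, discourse, inter-word dependence, or
real biomedical text quality — the grammar has none of those.

## Desk-scale studies

Two end-to-end studies (in `condlm.experiments`) size the problem to
minutes on one CPU; problem sizes are the studies' definition, not
externally imposed:

* **Memorization**: 16 short documents, tiny configuration (embedding 64,
  2 heads, 1 encoder / 2 decoder blocks), dropout 0, 700 Adam steps at
  3e-3 with 100-step warmup. Success: evaluated next-token loss on the
  full-document batch < 0.3, and greedy decoding from each probed title
  reproduces the memorized abstract token-for-token. Observed: loss
  ≈ 0.003–0.008, 4/4 reproduced.
* **Conditional control**: 500 documents from the 2-topic disjoint
  grammar, 170-piece vocabulary (large enough that every word keeps a
  single-piece form, so model probabilities aggregate cleanly to word
  space), dropout 0.1, 1000 steps. Success: total-variation distance
  between the model's next-token distribution (averaged over 10
  in-distribution contexts, residual non-word mass counted) and the
  grammar's exact conditional ≤ 0.15 per keyword, and generated text
  contains > 10× more own-topic than cross-topic words. Observed: TV
  ≈ 0.11–0.15 across seeds; cross-topic counts of 0.

## Known limitations

* Single-device, float64, no mixed precision or attention-efficiency
  variants; full-scale (16-layer, 14M-document) training is out of scope.
* The annotation provider is an interface: real POS/dependency/entity
  annotations must come from an external tool; the synthetic labels stand
  in structurally, not linguistically.
* METEOR lacks the synonym stage; Bleu/ROUGE as defined here are not
  comparable to toolkit scores (documented above by design).
* Offsets assume lowercasing preserves string length; exotic case-folding
  expansions (e.g. ß) could shift annotation spans by a character.
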
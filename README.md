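# condlm

Keyword- and year-conditioned language modeling for biomedical abstracts.

Biomedical papers often weave together a specific set of concepts — a gene,
a disease, a method — and those concepts are frequently recorded as
metadata keywords (MeSH descriptors or free strings) on MEDLINE citations.
`condlm` implements a conditional language model that lets the *user*
choose that concept set: a transformer whose shallow **encoder stack**
encodes an unordered set of condition embeddings (keywords plus the
publication year) and whose deep **decoder stack** generates abstract text
left-to-right under masked self-attention, attending to the encoded
conditions at every layer. The package covers the full workflow — data
preparation, training, generation, and evaluation — and ships a synthetic
corpus generator with closed-form statistics so the entire pipeline can be
exercised and verified on one CPU in minutes.

## The model

A language model factorizes Pr(s) = ∏ᵢ Pr(sᵢ | s₁…sᵢ₋₁); the conditional
variant adds a condition set *c*:

    Pr(s | c) = ∏ᵢ Pr(sᵢ | s₁…sᵢ₋₁, c)

Here *c* is the record's publication-year index plus one index per retained
metadata keyword (keywords seen fewer than 10 times in training are
pruned; years are indexed half-open up to a cutoff). The network is the
standard transformer built from scaled dot-product attention
A(Q,K,V) = softmax(QKᵀ/√d)V, multi-head mixing, position-wise ReLU
feed-forward expansions and post-norm residual blocks LayerNorm(f(x)+x).
Condition embeddings enter the encoder *without* positional encoding — a
condition set is unordered, and every model output is invariant to
permuting it (enforced by test). Token embeddings get the sinusoidal
positional code.

Training is multi-task: four linear heads on the final decoder states
predict, at each position, the next subword token **t**, and that token's
part-of-speech **p**, dependency relation **d**, and entity class **e**
(14 biomedical entity types + "not an entity"):

    L = L_T + L_P + L_D + L_E

each term a cross-entropy under teacher forcing (targets are the input
track shifted by one). Text is segmented by a unigram subword model
(16 000 pieces at full scale) with optional probabilistic segmentation for
subword regularization; training windows are 128 subword tokens starting
at sentence boundaries, resampled fresh each time a document is visited.

The evaluation suite implements sentence-wise n-gram recall metrics:
per-order Bleu (no brevity penalty), summed Bleu₁₊₂₊₃₊₄, ROUGE-L
(β = 1.2), CIDEr, a METEOR-style exact+stem matcher, and **CIDEr-Title**
— CIDEr with the TF-IDF weight of every n-gram that appears in the title
forced to zero, so parroting the prompt scores nothing.

## Worked example

Train a tiny model (embedding 64, 2 heads, 1 encoder + 2 decoder blocks)
on 400 synthetic documents drawn from two keyword topics with disjoint
word inventories, then generate from the same title under each condition:

```
$ python examples/04_conditional_generation.py
condition=topic_a: own-topic words 22, cross-topic words 0
    tojaku fopepe kelefo gibato jipihu humuva. ...
condition=topic_b: own-topic words 36, cross-topic words 0
    bucune tobabu zelifi nocoge dipelo fuhumu. ...
```

Every generated word comes from the conditioned topic's inventory and none
from the other topic — the conditioning pathway (encoder plus
cross-attention) is doing the steering, since both generations share the
same title prompt and the same decoder.

The other examples walk the remaining capabilities: `01` subword
vocabulary training and probabilistic segmentation, `02` corpus
filtering/splitting/indexing and window sampling, `03` the four-component
training loss, `05` the sentence-wise metric report (where a title-parrot
sentence scores 0.82 on plain CIDEr but exactly 0 on CIDEr-Title).

A thin CLI mirrors the pipeline stages:

```
condlm synth --docs 500 --seed 13 --out synth.jsonl
condlm vocab --input synth.jsonl --size 170 --out vocab.tsv --seed 13
condlm prep  --records synth.jsonl --out prep/ --split 0.7 --seed 13
condlm train --prep-dir prep/ --vocab vocab.tsv --out ckpt/ --seed 13
condlm generate --ckpt ckpt/ckpt_final.npz --vocab vocab.tsv \
    --conditions prep/conditions.json --title "some title" --keywords topic_a
condlm eval --generated gen.jsonl --references prep/test.jsonl --out report.tsv
```

## Layout

| path | contents |
| --- | --- |
| `src/condlm/subtoken.py` | unigram subword vocabulary + Viterbi/sampled segmentation |
| `src/condlm/corpus.py` | records, filtering, split, condition index, label alignment, windows |
| `src/condlm/medline_xml.py` | MEDLINE/PubMed XML reader |
| `src/condlm/autograd.py` | minimal reverse-mode autodiff over numpy |
| `src/condlm/model.py` | encoder/decoder transformer, four heads, multi-task loss, checkpoints |
| `src/condlm/trainer.py` | Adam/LAMB, warmup schedule, window resampling, exact resume |
| `src/condlm/generation.py` | temperature/top-k/top-p ancestral sampling |
| `src/condlm/metrics.py` | Bleu-k, ROUGE-L, CIDEr(+title-masked), METEOR-lite, report protocol |
| `src/condlm/synthetic.py` | condition-dependent grammar with closed-form statistics |
| `src/condlm/experiments.py` | desk-scale memorization / conditional-control studies |
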
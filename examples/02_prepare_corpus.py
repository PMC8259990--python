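"""Filter, split and index a citation corpus, then sample training windows.

Shows the data-preparation pipeline on synthetic records: English-language
filtering, the 70-30 train/test split, keyword pruning and year indexing,
and the sentence-aligned 128-token training windows with their four
shifted target tracks.
"""

import numpy as np

from condlm import (build_condition_index, build_document_track, build_vocab,
                    filter_records, sample_corpus, sample_window,
                    split_train_test)
from condlm.synthetic import default_grammar

grammar = default_grammar(n_words=60, n_topics=4, seed=2)
records = list(filter_records(sample_corpus(grammar, 400, rng=2)))
train, test = split_train_test(records, ratio=0.7, seed=13)
print(f"{len(records)} records -> {len(train)} train / {len(test)} test")

index = build_condition_index(train, min_count=10, cutoff_year=2020)
print(f"{index.n_keywords} keywords kept, {index.n_years} year indices, "
      f"{index.n_conditions} condition embeddings in total")

vocab = build_vocab([r.text for r in train], size=150, seed=13)
track = build_document_track(train[0], vocab, index)
window = sample_window(track, window=128, rng=np.random.default_rng(0))
print("window tokens:", len(window))
print("inputs head:  ", window.input_ids[:8])
print("targets head: ", window.token_targets[:8])
# token_targets is input_ids shifted by one: position i predicts token i+1
# (plus that token's POS, dependency and entity labels on the other tracks).
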
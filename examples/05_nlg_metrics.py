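"""Score a generated abstract sentence-by-sentence against its reference.

Demonstrates the evaluation protocol: the generated abstract is split into
sentences, each scored against the full set of reference sentences with
per-order Bleu, summed Bleu, ROUGE-L, CIDEr, the title-masked CIDEr
variant, and the METEOR-style stem-matching score.
"""

from condlm import evaluate_generation

title = "Gene expression in cancer cells"
reference = ("Gene expression changes drive cancer cell growth. "
             "We measured expression in tumor samples. "
             "Expression of target genes predicts outcome.")
generated = ("Gene expression in cancer cells. "
             "We measured many samples. "
             "Completely unrelated filler sentence here.")

report = evaluate_generation(generated, reference, title)
print(f"{report.n_sentences} generated sentences\n")
print(f"{'metric':<12} " + " ".join(f"s{i}" for i in range(report.n_sentences))
      + "   mean")
for name, scores in report.per_sentence.items():
    row = " ".join(f"{s:5.2f}" for s in scores)
    print(f"{name:<12} {row}   {report.mean[name]:5.2f}")
# Sentence 0 parrots the title: its plain CIDEr is high but its
# title-masked CIDEr drops toward zero, which is exactly the non-trivial-
# content signal that metric was designed to expose.  bleu_sum ranges over
# [0, 4] (it adds orders 1-4); the others live in [0, 1] except CIDEr's
# conventional x10 scale.
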
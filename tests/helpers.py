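"""Shared helpers for the test suite."""

from condlm.subtoken import SPECIALS, SubwordVocab


def make_vocab(pieces: dict[str, float]) -> SubwordVocab:
    """Hand-built vocabulary: the four specials plus explicit pieces."""
    return SubwordVocab([(p, 0.0) for p in SPECIALS] + sorted(pieces.items()))
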
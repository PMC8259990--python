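"""Conditional ancestral generation of abstracts from a title prompt.

The prompt is the start-of-abstract token followed by the segmented title;
the condition set is the publication-year index plus any retained keyword
indices (unknown keywords are dropped with a warning — they would have been
pruned from the index anyway).  Tokens are then drawn one at a time from
the model's next-token distribution, with optional temperature, top-k and
nucleus (top-p) shaping, until the end-of-abstract token appears or a
length cap is hit.  When the running sequence would exceed the model's
maximum length, a sliding window keeps the most recent tokens as context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import model as M
from .corpus import ConditionIndex
from .subtoken import SubwordVocab, detokenize, segment

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Next-token sampling behaviour; temperature 0 means greedy argmax."""

    temperature: float = 1.0
    top_k: int | None = None
    top_p: float | None = None
    max_new_tokens: int = 256
    seed: int = 13

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.top_p is not None and not 0.0 < self.top_p <= 1.0:
            raise ValueError("top_p must lie in (0, 1]")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def sample_next(logits: np.ndarray, config: SamplerConfig,
                rng: np.random.Generator) -> int:
    """Draw one token id from temperature/top-k/top-p-shaped logits."""
    logits = np.asarray(logits, dtype=np.float64).copy()
    finite = np.isfinite(logits)
    if not finite.any():
        raise ValueError("no token has finite probability")
    if config.temperature == 0.0:
        return int(np.argmax(np.where(finite, logits, -np.inf)))
    z = np.where(finite, logits / config.temperature, -np.inf)
    if config.top_k is not None:
        kth = np.sort(z)[-config.top_k]
        z = np.where(z >= kth, z, -np.inf)
    p = np.exp(z - z[np.isfinite(z)].max())
    p = p / p.sum()
    if config.top_p is not None and config.top_p < 1.0:
        order = np.argsort(-p)
        cum = np.cumsum(p[order])
        cutoff = int(np.searchsorted(cum, config.top_p)) + 1
        keep = order[:cutoff]
        mask = np.zeros_like(p)
        mask[keep] = p[keep]
        p = mask / mask.sum()
    return int(rng.choice(len(p), p=p))


def generate(title: str, keywords, year: int, params: M.ModelParams,
             vocab: SubwordVocab, cond_index: ConditionIndex,
             sampler: SamplerConfig | None = None) -> tuple[list[int], str]:
    """Generate an abstract conditioned on keywords and a publication year.

    Returns ``(token_ids, text)`` where both cover only the newly generated
    abstract (the title prompt is excluded) and ``text`` is the detokenized
    string.  Deterministic for a fixed sampler seed.
    """
    if not title or not title.strip():
        raise ValueError("generation requires a non-empty title")
    sampler = sampler or SamplerConfig()
    cfg = params.config
    rng = np.random.default_rng(sampler.seed)

    cond_ids = [cond_index.year_index(year)]
    for kw in keywords:
        idx = cond_index.keyword_index(kw)
        if idx is None:
            logger.warning("dropping unknown condition keyword %r", kw)
        else:
            cond_ids.append(idx)

    context = [vocab.soa_id] + segment(title, vocab)
    cond_arr = np.asarray([cond_ids], dtype=np.int64)
    cond_mask = np.ones_like(cond_arr, dtype=bool)
    generated: list[int] = []

    for _ in range(sampler.max_new_tokens):
        visible = context[-cfg.max_seq:]
        batch = M.Batch(
            token_ids=np.asarray([visible], dtype=np.int64),
            token_mask=np.ones((1, len(visible)), dtype=bool),
            cond_ids=cond_arr, cond_mask=cond_mask,
        )
        out = M.forward(batch, params, mode="eval")
        logits = out.token_logits.data[0, -1].copy()
        logits[vocab.pad_id] = -np.inf      # padding is never generated
        logits[vocab.soa_id] = -np.inf      # one abstract per generation
        nxt = sample_next(logits, sampler, rng)
        if nxt == vocab.eoa_id:
            generated.append(nxt)
            break
        generated.append(nxt)
        context.append(nxt)

    return generated, detokenize(generated, vocab)
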
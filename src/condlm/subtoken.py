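"""Unigram subword vocabulary and probabilistic segmentation.

Text is lowercased and segmented into pieces from a fixed-size vocabulary
under a unigram language model: a segmentation's score is the sum of its
pieces' log-probabilities.  Viterbi mode returns the single best
segmentation; sample mode draws segmentations with probability proportional
to ``exp(score / alpha)``, which is the subword-regularization scheme used
to diversify tokenizations during training (alpha -> 0 recovers Viterbi).

The vocabulary trainer is self-contained: it seeds candidates with every
observed character plus frequent substrings (word-boundary aware), then
refines piece log-probabilities with a few rounds of Viterbi EM and prunes
to the requested size.  Character coverage is enforced so that any string
over the observed alphabet remains segmentable; characters never seen in
training map to the unknown id.

Four special pieces occupy the first ids in fixed order: padding, unknown,
start-of-abstract and end-of-abstract.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

PAD_PIECE = "<pad>"
UNK_PIECE = "<unk>"
SOA_PIECE = "<s>"    # start of abstract
EOA_PIECE = "</s>"   # end of abstract
SPECIALS = (PAD_PIECE, UNK_PIECE, SOA_PIECE, EOA_PIECE)

_MAX_PIECE_LEN = 16
_UNK_PENALTY = -20.0


@dataclass
class SubwordVocab:
    """Fixed-size unigram piece inventory with log-probabilities.

    ``pieces[i]`` is ``(string, logp)`` for token id ``i``; ids 0..3 are the
    special tokens in the fixed order pad, unk, start, end.
    """

    pieces: list[tuple[str, float]]
    _piece_to_id: dict[str, int] = field(default=None, repr=False)  # type: ignore[assignment]
    _max_len: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if [p for p, _ in self.pieces[:4]] != list(SPECIALS):
            raise ValueError("first four pieces must be the special tokens "
                             f"{SPECIALS}")
        for piece, logp in self.pieces:
            if not (math.isfinite(logp) and logp <= 0.0):
                raise ValueError(f"piece {piece!r} has invalid log-prob {logp}")
        # specials are not matchable text pieces
        self._piece_to_id = {p: i for i, (p, _) in enumerate(self.pieces) if i >= 4}
        if len(self._piece_to_id) != len(self.pieces) - 4:
            raise ValueError("duplicate pieces in vocabulary")
        self._max_len = max((len(p) for p in self._piece_to_id), default=0)

    # -- ids -----------------------------------------------------------------
    @property
    def size(self) -> int:
        return len(self.pieces)

    pad_id = 0
    unk_id = 1
    soa_id = 2
    eoa_id = 3

    def piece(self, token_id: int) -> str:
        if not 0 <= token_id < self.size:
            raise ValueError(f"token id {token_id} out of range [0, {self.size})")
        return self.pieces[token_id][0]

    def logp(self, token_id: int) -> float:
        return self.pieces[token_id][1]

    def id_of(self, piece: str) -> int | None:
        return self._piece_to_id.get(piece)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str) -> None:
        """Write one ``piece<TAB>logp`` line per id (UTF-8, escaped)."""
        with open(path, "w", encoding="utf-8") as fh:
            for piece, logp in self.pieces:
                fh.write(f"{_escape(piece)}\t{logp!r}\n")

    @classmethod
    def load(cls, path: str) -> "SubwordVocab":
        pieces: list[tuple[str, float]] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                token, _, logp = line.rstrip("\n").partition("\t")
                pieces.append((_unescape(token), float(logp)))
        return cls(pieces)


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(s: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            nxt = s[i + 1]
            out.append({"\\": "\\", "t": "\t", "n": "\n"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# vocabulary training
# ---------------------------------------------------------------------------

def _candidate_substrings(sentences: list[str], limit: int) -> Counter:
    """Frequent word-boundary-aware substrings (words keep a leading space)."""
    counts: Counter = Counter()
    for sent in sentences:
        words = sent.split(" ")
        units: list[str] = []
        for j, w in enumerate(words):
            if not w:
                continue
            units.append(w if j == 0 else " " + w)
            if j > 0:
                units.append(w)  # bare variant so mid-text matches too
        for unit in units:
            n = len(unit)
            for i in range(n):
                for L in range(2, min(_MAX_PIECE_LEN, n - i) + 1):
                    counts[unit[i:i + L]] += 1
    if len(counts) > limit:
        counts = Counter(dict(counts.most_common(limit)))
    return counts


def _viterbi_ids(text: str, pieces: dict[str, float], max_len: int) -> list[str]:
    """Best segmentation of ``text`` into keys of ``pieces`` (chars covered)."""
    n = len(text)
    best = np.full(n + 1, -np.inf)
    best[0] = 0.0
    back: list[tuple[int, str] | None] = [None] * (n + 1)
    for j in range(1, n + 1):
        for L in range(1, min(max_len, j) + 1):
            piece = text[j - L:j]
            lp = pieces.get(piece)
            if lp is None:
                if L == 1:
                    lp = _UNK_PENALTY
                else:
                    continue
            s = best[j - L] + lp
            if s > best[j]:
                best[j] = s
                back[j] = (j - L, piece)
    out: list[str] = []
    j = n
    while j > 0:
        i, piece = back[j]  # type: ignore[misc]
        out.append(piece)
        j = i
    out.reverse()
    return out


def build_vocab(sentences, size: int = 16000, seed: int = 13,
                em_rounds: int = 3, max_train_sentences: int = 20000) -> SubwordVocab:
    """Train a unigram subword vocabulary of exactly ``size`` pieces.

    The corpus is lowercased internally.  Every character observed in the
    (sub)sampled training sentences is guaranteed its own piece; the
    remaining budget goes to frequent multi-character substrings whose
    log-probabilities are refined by Viterbi EM.

    Raises ``ValueError`` if ``size`` cannot cover all observed characters
    plus the four special tokens.
    """
    sentences = [s.lower() for s in sentences if s]
    if not sentences:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    rng = np.random.default_rng(seed)
    if len(sentences) > max_train_sentences:
        idx = rng.choice(len(sentences), size=max_train_sentences, replace=False)
        sentences = [sentences[i] for i in sorted(idx)]

    char_counts: Counter = Counter()
    for s in sentences:
        char_counts.update(s)
    chars = sorted(char_counts)
    minimum = len(chars) + len(SPECIALS)
    if size < minimum:
        raise ValueError(
            f"vocab size {size} too small for character coverage: need at "
            f"least {minimum} ({len(chars)} characters + {len(SPECIALS)} specials)")

    budget = size - len(SPECIALS)          # non-special pieces
    n_multi = budget - len(chars)          # slots for multi-char pieces

    cand = _candidate_substrings(sentences, limit=max(4 * budget, 1000))
    # initial inventory: chars (forced) + highest-scoring substrings
    scored = sorted(cand.items(), key=lambda kv: (-kv[1] * (len(kv[0]) - 1), kv[0]))
    inventory: dict[str, float] = {}
    total0 = sum(char_counts.values()) + sum(c for _, c in scored) + 1.0
    for ch in chars:
        inventory[ch] = math.log(char_counts[ch] / total0)
    for piece, c in scored[: 3 * max(n_multi, 0)]:
        if piece not in inventory:
            inventory[piece] = math.log(c / total0)

    max_len = max((len(p) for p in inventory), default=1)
    for round_no in range(em_rounds + 1):
        usage: Counter = Counter()
        for s in sentences:
            usage.update(_viterbi_ids(s, inventory, max_len))
        if round_no == em_rounds:
            break
        # M step: re-estimate probabilities from Viterbi usage; drop unused
        # multi-char pieces, keep all chars alive with a small floor count.
        kept: dict[str, float] = {}
        total = sum(usage.values()) + len(chars)
        for piece in inventory:
            c = usage.get(piece, 0)
            if len(piece) == 1 and piece in char_counts:
                kept[piece] = math.log((c + 1.0) / total)
            elif c > 0:
                kept[piece] = math.log(c / total)
        inventory = kept
        max_len = max((len(p) for p in inventory), default=1)

    multi = [(p, c) for p, c in usage.items()
             if len(p) > 1 and p in inventory]
    multi.sort(key=lambda kv: (-kv[1], kv[0]))
    chosen: dict[str, float] = {p: float(c) for p, c in multi[:max(n_multi, 0)]}
    if len(chosen) < n_multi:
        # EM retired more pieces than the budget requires; backfill with the
        # next-most-frequent raw substrings at a nominal count
        for piece, _ in sorted(cand.items(), key=lambda kv: (-kv[1], kv[0])):
            if len(chosen) >= n_multi:
                break
            if len(piece) > 1 and piece not in chosen:
                chosen[piece] = 0.5

    final_counts: dict[str, float] = {}
    for ch in chars:
        final_counts[ch] = usage.get(ch, 0) + 1.0
    for p, c in chosen.items():
        final_counts[p] = c
    total = sum(final_counts.values())
    pieces: list[tuple[str, float]] = [(sp, 0.0) for sp in SPECIALS]
    body = sorted(final_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    pieces.extend((p, math.log(c / total)) for p, c in body)
    assert len(pieces) == size
    return SubwordVocab(pieces)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _edges_into(text: str, j: int, vocab: SubwordVocab) -> list[tuple[int, int, float]]:
    """All lattice edges ending at position j: (start, token_id, logp)."""
    edges: list[tuple[int, int, float]] = []
    for L in range(1, min(vocab._max_len, j) + 1):
        piece = text[j - L:j]
        tid = vocab.id_of(piece)
        if tid is not None:
            edges.append((j - L, tid, vocab.logp(tid)))
    if not edges:
        edges.append((j - 1, vocab.unk_id, _UNK_PENALTY))
    return edges


def segment_with_offsets(text: str, vocab: SubwordVocab, mode: str = "viterbi",
                         alpha: float = 1.0,
                         seed: int | None = None) -> list[tuple[int, int, int]]:
    """Segment ``text`` and return ``(token_id, char_start, char_end)`` triples.

    Offsets refer to the lowercased text (lowercasing happens here; callers
    pass raw text).  ``mode`` is ``"viterbi"`` (best path, deterministic) or
    ``"sample"`` (path drawn with probability proportional to
    ``exp(score/alpha)``).
    """
    if mode not in ("viterbi", "sample"):
        raise ValueError(f"unknown segmentation mode {mode!r}")
    text = text.lower()
    if not text:
        raise ValueError("cannot segment an empty string")
    n = len(text)

    if mode == "sample" and alpha > 1e-4:
        inv_alpha = 1.0 / alpha
        fwd = np.full(n + 1, -np.inf)
        fwd[0] = 0.0
        all_edges = [_edges_into(text, j, vocab) for j in range(1, n + 1)]
        for j in range(1, n + 1):
            scores = [fwd[i] + lp * inv_alpha for i, _, lp in all_edges[j - 1]]
            fwd[j] = _logsumexp(scores)
        rng = np.random.default_rng(seed)
        out: list[tuple[int, int, int]] = []
        j = n
        while j > 0:
            edges = all_edges[j - 1]
            w = np.array([fwd[i] + lp * inv_alpha for i, _, lp in edges])
            w = np.exp(w - _logsumexp(list(w)))
            k = rng.choice(len(edges), p=w / w.sum())
            i, tid, _ = edges[k]
            out.append((tid, i, j))
            j = i
        out.reverse()
        return out

    # Viterbi (also the alpha -> 0 limit of sampling)
    best = np.full(n + 1, -np.inf)
    best[0] = 0.0
    back: list[tuple[int, int] | None] = [None] * (n + 1)
    for j in range(1, n + 1):
        for i, tid, lp in _edges_into(text, j, vocab):
            s = best[i] + lp
            if s > best[j]:
                best[j] = s
                back[j] = (i, tid)
    out = []
    j = n
    while j > 0:
        i, tid = back[j]  # type: ignore[misc]
        out.append((tid, i, j))
        j = i
    out.reverse()
    return out


def segment(text: str, vocab: SubwordVocab, mode: str = "viterbi",
            alpha: float = 1.0, seed: int | None = None) -> list[int]:
    """Token ids of the (lowercased) text; see :func:`segment_with_offsets`."""
    return [tid for tid, _, _ in segment_with_offsets(text, vocab, mode, alpha, seed)]


def detokenize(ids, vocab: SubwordVocab) -> str:
    """Concatenate piece strings, dropping special tokens."""
    out: list[str] = []
    for tid in ids:
        tid = int(tid)
        if not 0 <= tid < vocab.size:
            raise ValueError(f"token id {tid} out of range [0, {vocab.size})")
        if tid >= 4:
            out.append(vocab.piece(tid))
    return "".join(out)


def _logsumexp(xs) -> float:
    m = max(xs)
    if m == -np.inf:
        return -np.inf
    return m + math.log(sum(math.exp(x - m) for x in xs))
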
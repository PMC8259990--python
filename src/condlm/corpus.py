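"""Citation records, filtering, splitting, condition indexing and windows.

A record is one MEDLINE-style citation: title, abstract, publication year,
an optional set of author-supplied keywords (MeSH descriptors or free
strings) and optional word-level annotations (POS, dependency relation,
entity class) from an external annotation provider.

Conditions — the keyword strings and the publication year — are mapped to a
contiguous embedding index space: index 0 is condition padding, then one
index per retained keyword (those occurring at least ``min_count`` times in
the training partition; rarer keywords are pruned), then one index per year
in the half-open range ``[min_year, cutoff_year)``.  With the earliest
training year 1790 and cutoff 2020 this yields 230 year indices.

Training examples are windows of at most ``window`` subword tokens whose
first token is the first token of a sentence; every window carries four
target tracks shifted by one position (teacher forcing), so position ``i``
predicts the next token and that next token's POS/dependency/entity labels.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from hashlib import blake2b

import numpy as np

from . import labels as L
from .subtoken import SubwordVocab, segment_with_offsets

logger = logging.getLogger(__name__)

_ENGLISH = {"eng", "en", "english"}


@dataclass
class WordAnnotation:
    """One annotated word: character span plus its three labels.

    Spans index into the record's document text (``title + " " + abstract``,
    lowercase); ``entity`` is ``"O"`` for words outside any entity mention.
    """

    start: int
    end: int
    pos: str
    dep: str
    entity: str = L.NOT_ENTITY

    def to_list(self) -> list:
        return [self.start, self.end, self.pos, self.dep, self.entity]

    @classmethod
    def from_list(cls, raw) -> "WordAnnotation":
        return cls(int(raw[0]), int(raw[1]), raw[2], raw[3], raw[4])


@dataclass
class MedlineRecord:
    """One citation: title, abstract, year, keywords, optional annotations."""

    id: str
    title: str
    abstract: str
    year: int
    keywords: set[str] = field(default_factory=set)
    language: str = "eng"
    annotations: list[WordAnnotation] | None = None

    @property
    def text(self) -> str:
        """Document text with the title as the first sentence."""
        return f"{self.title} {self.abstract}".strip()

    def to_dict(self) -> dict:
        d = {
            "id": self.id, "title": self.title, "abstract": self.abstract,
            "year": self.year, "keywords": sorted(self.keywords),
            "language": self.language,
        }
        if self.annotations is not None:
            d["annotations"] = [a.to_list() for a in self.annotations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MedlineRecord":
        ann = d.get("annotations")
        return cls(
            id=str(d["id"]), title=d["title"], abstract=d["abstract"],
            year=int(d["year"]), keywords=set(d.get("keywords", ())),
            language=d.get("language", "eng"),
            annotations=None if ann is None
            else [WordAnnotation.from_list(a) for a in ann],
        )


def read_jsonl(path: str) -> list[MedlineRecord]:
    with open(path, encoding="utf-8") as fh:
        return [MedlineRecord.from_dict(json.loads(line))
                for line in fh if line.strip()]


def write_jsonl(records, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# sentences
# ---------------------------------------------------------------------------

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9a-z])")


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences (rule-based: terminator + whitespace)."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        if m.start() > start:
            spans.append((start, m.start()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def split_sentences(text: str) -> list[str]:
    return [text[a:b] for a, b in sentence_spans(text)]


# ---------------------------------------------------------------------------
# filtering and splitting
# ---------------------------------------------------------------------------

def filter_records(records):
    """Keep English records with at least one non-title sentence.

    Records without keywords are retained.  Dropped records are counted and
    logged, never raised.
    """
    dropped = 0
    for rec in records:
        if rec.language.strip().lower() not in _ENGLISH:
            dropped += 1
            continue
        if not split_sentences(rec.abstract.strip()):
            dropped += 1
            continue
        yield rec
    if dropped:
        logger.info("filter_records: dropped %d records", dropped)


def split_train_test(records, ratio: float = 0.7, seed: int = 13,
                     ) -> tuple[list[MedlineRecord], list[MedlineRecord]]:
    """Deterministic 70-30-style split keyed on record ids.

    Records are ordered by a seeded hash of their id and cut at
    ``round(ratio * n)``, so the partition is exhaustive, disjoint, exact to
    within one record of the requested ratio, and a pure function of the id
    set and seed.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot split an empty record set")
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must lie in (0, 1), got {ratio}")
    key = str(seed).encode()

    def rank(rec: MedlineRecord) -> bytes:
        return blake2b(rec.id.encode(), key=key, digest_size=8).digest()

    ordered = sorted(records, key=rank)
    n_train = int(round(ratio * len(records)))
    n_train = min(max(n_train, 1), len(records) - 1)
    return ordered[:n_train], ordered[n_train:]


# ---------------------------------------------------------------------------
# condition indexing
# ---------------------------------------------------------------------------

PAD_CONDITION = 0


@dataclass
class ConditionIndex:
    """Maps keyword strings and years to condition-embedding indices.

    Index 0 is condition padding; keyword indices follow, then year indices
    for the half-open range ``[min_year, cutoff_year)``.  Years at or beyond
    the cutoff clamp to the final year index; years before ``min_year``
    clamp to the first.
    """

    keyword_to_index: dict[str, int]
    min_year: int
    cutoff_year: int
    min_keyword_count: int

    @property
    def n_keywords(self) -> int:
        return len(self.keyword_to_index)

    @property
    def n_years(self) -> int:
        return self.cutoff_year - self.min_year

    @property
    def n_conditions(self) -> int:
        """Total embedding rows: padding + keywords + years."""
        return 1 + self.n_keywords + self.n_years

    def year_index(self, year: int) -> int:
        year = min(max(year, self.min_year), self.cutoff_year - 1)
        return 1 + self.n_keywords + (year - self.min_year)

    def keyword_index(self, keyword: str) -> int | None:
        return self.keyword_to_index.get(_norm_keyword(keyword))

    def condition_ids(self, record: MedlineRecord) -> list[int]:
        """Year index plus indices of the record's retained keywords."""
        ids = [self.year_index(record.year)]
        for kw in sorted(record.keywords):
            idx = self.keyword_index(kw)
            if idx is not None:
                ids.append(idx)
        return ids


def _norm_keyword(kw: str) -> str:
    return kw.strip().lower()


def build_condition_index(train_records, min_count: int = 10,
                          cutoff_year: int = 2020) -> ConditionIndex:
    """Index keywords (pruning those seen fewer than ``min_count`` times)
    and years of the training partition."""
    train_records = list(train_records)
    if not train_records:
        raise ValueError("cannot build a condition index from no records")
    counts: dict[str, int] = {}
    min_year = None
    for rec in train_records:
        if min_year is None or rec.year < min_year:
            min_year = rec.year
        for kw in rec.keywords:
            k = _norm_keyword(kw)
            counts[k] = counts.get(k, 0) + 1
    kept = sorted(k for k, c in counts.items() if c >= min_count)
    keyword_to_index = {k: i + 1 for i, k in enumerate(kept)}
    if min_year >= cutoff_year:
        raise ValueError(f"earliest year {min_year} not below cutoff {cutoff_year}")
    return ConditionIndex(keyword_to_index=keyword_to_index,
                          min_year=int(min_year), cutoff_year=int(cutoff_year),
                          min_keyword_count=int(min_count))


# ---------------------------------------------------------------------------
# label alignment
# ---------------------------------------------------------------------------

def align_labels(annotations: list[WordAnnotation],
                 segments: list[tuple[int, int, int]],
                 text: str | None = None,
                 ) -> tuple[list[int], list[int], list[int]]:
    """Per-subword POS/dependency/entity label ids.

    Each subword inherits the labels of the annotated word whose span
    contains the subword's first character (leading whitespace inside a
    piece is skipped when ``text`` is given, since word-boundary pieces
    carry their preceding space); subwords outside every span get the
    fallback labels (entity: "not an entity").  Overlapping annotation
    spans violate the provider contract and raise ``ValueError``.
    """
    anns = sorted(annotations, key=lambda a: (a.start, a.end))
    for prev, cur in zip(anns, anns[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping annotation spans [{prev.start},{prev.end}) and "
                f"[{cur.start},{cur.end})")
    starts = [a.start for a in anns]
    pos_ids: list[int] = []
    dep_ids: list[int] = []
    ent_ids: list[int] = []
    j = 0
    for _, char_start, char_end in segments:
        if text is not None:
            while char_start < char_end - 1 and text[char_start].isspace():
                char_start += 1
        while j + 1 < len(anns) and starts[j + 1] <= char_start:
            j += 1
        hit = anns[j] if anns and anns[j].start <= char_start < anns[j].end else None
        if hit is None:
            pos_ids.append(L.POS_TO_ID[L.FALLBACK_POS])
            dep_ids.append(L.DEP_TO_ID[L.FALLBACK_DEP])
            ent_ids.append(L.ENTITY_TO_ID[L.FALLBACK_ENTITY])
        else:
            pos_ids.append(L.POS_TO_ID.get(hit.pos, L.POS_TO_ID[L.FALLBACK_POS]))
            dep_ids.append(L.DEP_TO_ID.get(hit.dep, L.DEP_TO_ID[L.FALLBACK_DEP]))
            ent_ids.append(L.ENTITY_TO_ID.get(hit.entity,
                                              L.ENTITY_TO_ID[L.FALLBACK_ENTITY]))
    return pos_ids, dep_ids, ent_ids


# ---------------------------------------------------------------------------
# document tracks and training windows
# ---------------------------------------------------------------------------

@dataclass
class DocumentTrack:
    """Aligned per-token tracks for one document plus sentence starts.

    Tokens are ``<s> title abstract </s>`` with the title counted as the
    first sentence; ``sentence_starts`` are token indices (position 0, the
    start token, opens the title sentence).
    """

    token_ids: list[int]
    pos_ids: list[int]
    dep_ids: list[int]
    ent_ids: list[int]
    sentence_starts: list[int]
    condition_ids: list[int]


@dataclass
class TrainingWindow:
    """One training example: inputs plus four shifted target tracks."""

    input_ids: list[int]
    token_targets: list[int]
    pos_targets: list[int]
    dep_targets: list[int]
    ent_targets: list[int]
    condition_ids: list[int]

    def __post_init__(self) -> None:
        n = len(self.input_ids)
        for track in (self.token_targets, self.pos_targets,
                      self.dep_targets, self.ent_targets):
            if len(track) != n:
                raise ValueError("all window tracks must share one length")
        if not self.condition_ids:
            raise ValueError("a window needs at least one condition id")

    def __len__(self) -> int:
        return len(self.input_ids)


def build_document_track(record: MedlineRecord, vocab: SubwordVocab,
                         cond_index: ConditionIndex, mode: str = "viterbi",
                         alpha: float = 1.0,
                         seed: int | None = None) -> DocumentTrack:
    """Tokenize a record sentence-by-sentence and attach aligned labels."""
    text = record.text.lower()
    spans = sentence_spans(text)
    if not spans:
        raise ValueError(f"record {record.id} has no sentences")
    token_ids: list[int] = [vocab.soa_id]
    segments: list[tuple[int, int, int]] = []
    sentence_starts: list[int] = [0]  # <s> opens the title sentence
    for i, (a, b) in enumerate(spans):
        if i > 0:
            sentence_starts.append(len(token_ids))
        sent_seed = None if seed is None else (seed + i) % (2 ** 31)
        for tid, s, e in segment_with_offsets(text[a:b], vocab, mode=mode,
                                              alpha=alpha, seed=sent_seed):
            token_ids.append(tid)
            segments.append((tid, a + s, a + e))
    token_ids.append(vocab.eoa_id)

    if record.annotations:
        pos_ids, dep_ids, ent_ids = align_labels(record.annotations, segments,
                                                 text=text)
    else:
        n = len(segments)
        pos_ids = [L.POS_TO_ID[L.FALLBACK_POS]] * n
        dep_ids = [L.DEP_TO_ID[L.FALLBACK_DEP]] * n
        ent_ids = [L.ENTITY_TO_ID[L.FALLBACK_ENTITY]] * n
    pad_pos = L.POS_TO_ID[L.FALLBACK_POS]
    pad_dep = L.DEP_TO_ID[L.FALLBACK_DEP]
    pad_ent = L.ENTITY_TO_ID[L.FALLBACK_ENTITY]
    return DocumentTrack(
        token_ids=token_ids,
        pos_ids=[pad_pos] + pos_ids + [pad_pos],
        dep_ids=[pad_dep] + dep_ids + [pad_dep],
        ent_ids=[pad_ent] + ent_ids + [pad_ent],
        sentence_starts=sentence_starts,
        condition_ids=cond_index.condition_ids(record),
    )


def full_window(track: DocumentTrack, window: int = 128,
                eoa_id: int = 3) -> TrainingWindow:
    """Deterministic window from the document head (title first)."""
    rng = np.random.default_rng(0)
    first_only = DocumentTrack(
        token_ids=track.token_ids, pos_ids=track.pos_ids,
        dep_ids=track.dep_ids, ent_ids=track.ent_ids,
        sentence_starts=[0], condition_ids=track.condition_ids)
    return sample_window(first_only, window=window, rng=rng, eoa_id=eoa_id)


def sample_window(track: DocumentTrack, window: int = 128,
                  rng: np.random.Generator | None = None,
                  eoa_id: int = 3) -> TrainingWindow:
    """Draw a training window starting at a uniformly chosen sentence start.

    Targets are the source tracks shifted left by one; when the window runs
    past the end of the document the final token target is the
    end-of-abstract id and label targets fall back to the null labels.
    """
    n = len(track.token_ids)
    if n < 2:
        raise ValueError("document must contain at least two tokens")
    rng = rng or np.random.default_rng()
    eligible = [s for s in track.sentence_starts if s < n - 1]
    if not eligible:
        raise ValueError("document has no eligible sentence starts")
    start = int(eligible[rng.integers(len(eligible))])
    end = min(start + window, n)
    inputs = track.token_ids[start:end]
    m = len(inputs)

    def shifted(src: list[int], pad: int) -> list[int]:
        out = src[start + 1:start + m + 1]
        return out + [pad] * (m - len(out))

    return TrainingWindow(
        input_ids=inputs,
        token_targets=shifted(track.token_ids, eoa_id),
        pos_targets=shifted(track.pos_ids, L.POS_TO_ID[L.FALLBACK_POS]),
        dep_targets=shifted(track.dep_ids, L.DEP_TO_ID[L.FALLBACK_DEP]),
        ent_targets=shifted(track.ent_ids, L.ENTITY_TO_ID[L.FALLBACK_ENTITY]),
        condition_ids=list(track.condition_ids),
    )
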
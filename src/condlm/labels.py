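"""Label inventories for the three auxiliary tagging tracks.

The decoder predicts, alongside the next subword token, the part-of-speech
tag, dependency relation and entity class of the *current* token.  Entity
classes follow the 14-type biomedical inventory used for cancer-genetics
named-entity annotation (cancer, organ, tissue, ... cellular component),
plus an explicit "not an entity" class, for 15 classes in total.  POS tags
are the universal tag set; dependency relations are a compact UD-style set.

Any annotation provider may be used as long as its labels are drawn from
these inventories; the synthetic corpus generator emits them directly.
"""

from __future__ import annotations

ENTITY_CLASSES: tuple[str, ...] = (
    "CANCER",
    "ORGAN",
    "TISSUE",
    "ORGANISM",
    "CELL",
    "AMINO_ACID",
    "GENE_OR_GENE_PRODUCT",
    "SIMPLE_CHEMICAL",
    "ANATOMICAL_SYSTEM",
    "IMMATERIAL_ANATOMICAL_ENTITY",
    "MULTI_TISSUE_STRUCTURE",
    "DEVELOPING_ANATOMICAL_STRUCTURE",
    "ORGANISM_SUBDIVISION",
    "CELLULAR_COMPONENT",
)

NOT_ENTITY = "O"

#: full entity label vocabulary: 14 typed classes + "not an entity"
ENTITY_LABELS: tuple[str, ...] = ENTITY_CLASSES + (NOT_ENTITY,)

POS_TAGS: tuple[str, ...] = (
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
)

DEP_TAGS: tuple[str, ...] = (
    "ROOT", "nsubj", "obj", "iobj", "amod", "advmod", "det", "case", "cc",
    "conj", "punct", "mark", "nmod", "compound", "xcomp", "ccomp", "aux",
    "cop", "dep",
)

ENTITY_TO_ID: dict[str, int] = {lab: i for i, lab in enumerate(ENTITY_LABELS)}
POS_TO_ID: dict[str, int] = {lab: i for i, lab in enumerate(POS_TAGS)}
DEP_TO_ID: dict[str, int] = {lab: i for i, lab in enumerate(DEP_TAGS)}

#: fallback labels for subwords not covered by any annotated word
#: (special tokens, stray whitespace/punctuation)
FALLBACK_POS = "X"
FALLBACK_DEP = "dep"
FALLBACK_ENTITY = NOT_ENTITY
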
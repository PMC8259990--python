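"""Reader for MEDLINE/PubMed XML citation exports.

Maps ``PubmedArticle`` elements onto :class:`~condlm.corpus.MedlineRecord`:
PMID, ArticleTitle, the concatenated AbstractText sections, the publication
year (``PubDate/Year``, falling back to the leading digits of
``MedlineDate``), the language tag, and the union of MeSH descriptor names
and author-supplied keywords.  Records without a title, abstract or
resolvable year are skipped.
"""

from __future__ import annotations

import logging
import re

from lxml import etree

from .corpus import MedlineRecord

logger = logging.getLogger(__name__)


def _text(node) -> str:
    return "".join(node.itertext()).strip() if node is not None else ""


def _year(article) -> int | None:
    y = article.find(".//Article/Journal/JournalIssue/PubDate/Year")
    if y is not None and _text(y).isdigit():
        return int(_text(y))
    md = article.find(".//Article/Journal/JournalIssue/PubDate/MedlineDate")
    if md is not None:
        m = re.search(r"\b(1[5-9]\d{2}|20\d{2})\b", _text(md))
        if m:
            return int(m.group(1))
    return None


def read_medline_xml(path: str) -> list[MedlineRecord]:
    """Parse a MEDLINE XML file into citation records."""
    tree = etree.parse(path)
    records: list[MedlineRecord] = []
    skipped = 0
    for article in tree.iter("PubmedArticle"):
        pmid = _text(article.find(".//MedlineCitation/PMID"))
        title = _text(article.find(".//Article/ArticleTitle"))
        abstract = " ".join(
            _text(a) for a in article.findall(".//Article/Abstract/AbstractText")
        ).strip()
        year = _year(article)
        if not (pmid and title and abstract and year):
            skipped += 1
            continue
        language = _text(article.find(".//Article/Language")) or "eng"
        keywords: set[str] = set()
        for d in article.findall(".//MeshHeadingList/MeshHeading/DescriptorName"):
            if _text(d):
                keywords.add(_text(d))
        for k in article.findall(".//KeywordList/Keyword"):
            if _text(k):
                keywords.add(_text(k))
        records.append(MedlineRecord(id=pmid, title=title, abstract=abstract,
                                     year=year, keywords=keywords,
                                     language=language))
    if skipped:
        logger.info("read_medline_xml: skipped %d incomplete citations", skipped)
    return records
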
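"""Publication records, corpora and GEO linkage.

A corpus is an ordered list of publication records whose order is the
retrieval order of the upstream source (e.g. PubMed relevance ranking);
this module consumes that order, it never recomputes it.  Records carry
the per-publication metadata set: identifier, title, authors, journal,
publication date, MeSH headings, linked GEO series and platform
accessions, raw download links, and the labels of analyses performed
downstream on each publication/series pair.

Live NCBI access is deliberately kept behind the *fetcher* contract of
:func:`build_corpus_from_pmids` so that everything here runs offline
against fixture stores.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Mapping, TextIO, Union

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "PubRecord",
    "Corpus",
    "parse_records",
    "build_corpus_from_pmids",
    "extract_gse_links",
    "mesh_term_counts",
    "limit_corpus",
    "write_corpus_jsonl",
    "write_corpus_tsv",
]

GSE_RE = re.compile(r"GSE[0-9]+")
GPL_RE = re.compile(r"^GPL[0-9]+$")

Source = Union[str, Path, TextIO]

_LIST_FIELDS = (
    "authors",
    "mesh_headings",
    "gse_codes",
    "platforms",
    "ftp_links",
    "analyses",
)


@dataclass
class PubRecord:
    """Metadata for one publication."""

    pmid: str
    title: str = ""
    authors: list[str] = field(default_factory=list)
    journal: str = ""
    pub_date: str | None = None
    mesh_headings: list[str] = field(default_factory=list)
    gse_codes: list[str] = field(default_factory=list)
    platforms: list[str] = field(default_factory=list)
    ftp_links: list[str] = field(default_factory=list)
    analyses: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if self.pub_date is not None:
            _dt.date.fromisoformat(self.pub_date)  # yyyy-mm-dd or raise
        for gse in self.gse_codes:
            if not re.match(r"^GSE[0-9]+$", gse):
                raise ValueError(f"invalid GEO series accession {gse!r}")
        for gpl in self.platforms:
            if not GPL_RE.match(gpl):
                raise ValueError(f"invalid GEO platform accession {gpl!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Corpus:
    """Ordered publication records plus provenance."""

    records: list[PubRecord]
    query: str = ""
    source_tag: str = ""

    def __post_init__(self) -> None:
        pmids = [r.pmid for r in self.records]
        if len(pmids) != len(set(pmids)):
            raise ValueError("duplicate pmids in corpus")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def pmids(self) -> list[str]:
        return [r.pmid for r in self.records]


# -- parsing ------------------------------------------------------------


def _as_stream(source: Source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


_MONTHS = {m: i for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"], 1)}


def _xml_date(elem) -> str | None:
    if elem is None:
        return None
    year = elem.findtext("Year")
    month = elem.findtext("Month")
    day = elem.findtext("Day")
    if not (year and month and day):
        return None
    if month in _MONTHS:
        month = f"{_MONTHS[month]:02d}"
    try:
        return _dt.date(int(year), int(month), int(day)).isoformat()
    except ValueError:
        return None


def _record_from_xml(article) -> PubRecord | None:
    cit = article.find("MedlineCitation")
    if cit is None:
        return None
    pmid = cit.findtext("PMID")
    if not pmid:
        return None
    art = cit.find("Article")
    title = art.findtext("ArticleTitle", default="") if art is not None else ""
    journal = art.findtext("Journal/Title", default="") if art is not None else ""
    authors: list[str] = []
    if art is not None:
        for a in art.findall("AuthorList/Author"):
            last, initials = a.findtext("LastName"), a.findtext("Initials")
            collective = a.findtext("CollectiveName")
            if last:
                authors.append(f"{last} {initials}" if initials else last)
            elif collective:
                authors.append(collective)
    pub_date = None
    if art is not None:
        pub_date = _xml_date(art.find("ArticleDate")) or _xml_date(
            art.find("Journal/JournalIssue/PubDate")
        )
    headings = [
        h.findtext("DescriptorName", default="").strip()
        for h in cit.findall("MeshHeadingList/MeshHeading")
    ]
    headings = [h for h in headings if h]
    accessions: list[str] = []
    if art is not None:
        for acc in art.findall("DataBankList/DataBank/AccessionNumberList/AccessionNumber"):
            if acc.text:
                accessions.append(acc.text.strip())
    gse = extract_gse_links(accessions)
    platforms = [a for a in accessions if GPL_RE.match(a)]
    return PubRecord(
        pmid=pmid.strip(),
        title=title or "",
        authors=authors,
        journal=journal or "",
        pub_date=pub_date,
        mesh_headings=headings,
        gse_codes=gse,
        platforms=platforms,
    )


def parse_records(source: Source, dialect: str = "json") -> Corpus:
    """Parse a record stream into a :class:`Corpus`, order preserved.

    Dialects: ``json`` — JSON-lines, one record object per line using the
    metadata field names; ``medline-xml`` — a PubmedArticleSet document.
    Records without a PMID and repeated PMIDs are dropped with a warning.
    """
    records: list[PubRecord] = []
    seen: set[str] = set()

    def _add(rec: PubRecord | None, where: str) -> None:
        if rec is None:
            logger.warning("record without PMID skipped (%s)", where)
            return
        if rec.pmid in seen:
            logger.warning("duplicate PMID %s dropped (%s)", rec.pmid, where)
            return
        seen.add(rec.pmid)
        records.append(rec)

    if dialect == "json":
        stream, close = _as_stream(source)
        try:
            for lineno, line in enumerate(stream, 1):
                if not line.strip():
                    continue
                payload = json.loads(line)
                if not payload.get("pmid"):
                    _add(None, f"line {lineno}")
                    continue
                kwargs = {
                    "pmid": str(payload["pmid"]),
                    "title": payload.get("title", ""),
                    "journal": payload.get("journal", ""),
                    "pub_date": payload.get("pub_date"),
                }
                for name in _LIST_FIELDS:
                    kwargs[name] = list(payload.get(name, []))
                _add(PubRecord(**kwargs), f"line {lineno}")
        finally:
            if close:
                stream.close()
    elif dialect == "medline-xml":
        if isinstance(source, (str, Path)):
            root = etree.parse(str(source)).getroot()
        else:
            data = source.read()
            root = etree.fromstring(data.encode() if isinstance(data, str) else data)
        for i, article in enumerate(root.findall(".//PubmedArticle"), 1):
            _add(_record_from_xml(article), f"article {i}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return Corpus(records=records, source_tag=f"parse:{dialect}")


Fetcher = Union[Callable[[str], PubRecord | None], Mapping[str, PubRecord]]


def build_corpus_from_pmids(
    pmids: Iterable[str], fetcher: Fetcher
) -> tuple[Corpus, list[str]]:
    """Build a corpus from an explicit PMID list, in the given order.

    *fetcher* is either a mapping ``pmid -> PubRecord`` (a fixture store)
    or a callable returning ``None`` for unresolvable pmids (e.g. a live
    retrieval adapter).  Returns the corpus and the list of pmids that
    could not be resolved.
    """
    pmids = list(pmids)
    if not pmids:
        raise ValueError("pmid list must be non-empty")
    fetch = fetcher.get if isinstance(fetcher, Mapping) else fetcher
    records, missing, seen = [], [], set()
    for pmid in pmids:
        if pmid in seen:
            continue
        seen.add(pmid)
        rec = fetch(pmid)
        if rec is None:
            missing.append(pmid)
            logger.warning("pmid %s unresolvable", pmid)
        else:
            records.append(rec)
    if not records:
        raise ValueError("no pmid could be resolved")
    return Corpus(records=records, query=";".join(pmids), source_tag="pmid-list"), missing


def extract_gse_links(raw_link_fields: Iterable[str]) -> list[str]:
    """Harvest GEO series accessions from free-text link fields.

    Every substring matching ``GSE[0-9]+`` is captured once, in order of
    first appearance.
    """
    out: list[str] = []
    seen: set[str] = set()
    for text in raw_link_fields:
        for m in GSE_RE.finditer(text or ""):
            if m.group() not in seen:
                seen.add(m.group())
                out.append(m.group())
    return out


def mesh_term_counts(corpus: Corpus) -> dict[str, int]:
    """Number of distinct records annotated with each heading.

    A heading repeated within one record contributes once.
    """
    counts: dict[str, int] = {}
    for rec in corpus:
        for term in set(rec.mesh_headings):
            counts[term] = counts.get(term, 0) + 1
    return counts


def limit_corpus(corpus: Corpus, n: int) -> Corpus:
    """First *n* records in retrieval order (all records when n >= size)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return Corpus(
        records=list(corpus.records[:n]),
        query=corpus.query,
        source_tag=corpus.source_tag,
    )


# -- writers ------------------------------------------------------------

_TSV_COLUMNS = (
    "pmid", "title", "authors", "journal", "pub_date",
    "mesh_headings", "gse_codes", "platforms", "ftp_links", "analyses",
)


def write_corpus_jsonl(corpus: Corpus, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")


def write_corpus_tsv(corpus: Corpus, path: Union[str, Path]) -> None:
    """One row per record; list fields semicolon-joined."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for rec in corpus:
            d = rec.to_dict()
            row = []
            for col in _TSV_COLUMNS:
                v = d[col]
                if isinstance(v, list):
                    row.append(";".join(v))
                else:
                    row.append("" if v is None else str(v))
            fh.write("\t".join(row) + "\n")
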
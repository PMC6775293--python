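"""Corpus construction from PubMed-style XML.

Reads semi-structured article records (``<pmid>``/``<PMID>`` plus
``<abstract>``/``<AbstractText>`` located by local tag name, so both flat
fixture files and standard PubmedArticle records parse), applies the
preprocessing chain (segmentation, lowercasing, lemmatization, stop-word
removal), and encodes documents over a dense integer vocabulary for the
topic model.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from lxml import etree

from .lemmatize import lemmatize

_TOKEN_RE = re.compile(r"[a-z]+")


class XmlParseError(ValueError):
    """Raised for malformed XML, naming the file and position."""


@dataclass
class Document:
    """One abstract: identifier, publication year, raw text, and its tokens."""

    pmid: str
    year: int
    raw_text: str
    tokens: list[str] = field(default_factory=list)
    token_ids: list[int] | None = None


class Vocabulary:
    """Bijective term <-> dense integer id mapping with document frequencies."""

    def __init__(self, terms: list[str], df: list[int] | None = None):
        self._terms = list(terms)
        self._ids = {t: i for i, t in enumerate(self._terms)}
        if len(self._ids) != len(self._terms):
            raise ValueError("duplicate terms in vocabulary")
        self.df = list(df) if df is not None else [0] * len(self._terms)

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term: str) -> bool:
        return term in self._ids

    def id(self, term: str) -> int:
        return self._ids[term]

    def term(self, idx: int) -> str:
        return self._terms[idx]

    @property
    def terms(self) -> list[str]:
        return list(self._terms)

    def encode(self, tokens: list[str]) -> list[int]:
        return [self._ids[t] for t in tokens if t in self._ids]

    def decode(self, ids: list[int]) -> list[str]:
        return [self._terms[i] for i in ids]


@dataclass
class Corpus:
    """Encoded documents over a shared vocabulary; ``year`` may be "pooled"."""

    documents: list[Document]
    vocabulary: Vocabulary
    year: int | str = "pooled"
    n_dropped: int = 0

    @property
    def M(self) -> int:
        return len(self.documents)

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    @property
    def n_tokens(self) -> int:
        return sum(len(d.token_ids) for d in self.documents)


def _local(elem) -> str:
    return etree.QName(elem).localname.lower() if isinstance(elem.tag, str) else ""


def _first_text(record, names: tuple[str, ...]) -> str:
    for elem in record.iter():
        if _local(elem) in names:
            return re.sub(r"\s+", " ", "".join(elem.itertext())).strip()
    return ""


def read_pubmed_xml(path: str | Path, year: int) -> tuple[list[Document], int]:
    """Parse one XML file into Documents; returns (documents, n_skipped).

    A record is a child of the root containing a pmid descendant (or the root
    itself for single-record files). Records missing a non-empty pmid or
    abstract are skipped and counted.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(
            f"malformed XML in {path} at line {exc.lineno}, column "
            f"{exc.position[1] if exc.position else '?'}: {exc.msg}"
        ) from exc
    root = tree.getroot()

    records = [
        child
        for child in root
        if isinstance(child.tag, str)
        and any(_local(e) == "pmid" for e in child.iter())
    ]
    if not records and any(_local(e) == "pmid" for e in root.iter()):
        records = [root]

    documents: list[Document] = []
    skipped = 0
    for record in records:
        pmid = _first_text(record, ("pmid",))
        abstract = _first_text(record, ("abstract",)) or _first_text(
            record, ("abstracttext",)
        )
        if not pmid or not abstract:
            skipped += 1
            continue
        documents.append(Document(pmid=pmid, year=year, raw_text=abstract))
    if not documents:
        warnings.warn(f"no usable records in {path}", stacklevel=2)
    return documents, skipped


def load_stopwords(path: str | Path | None = None) -> set[str]:
    """Load a one-word-per-line stop list; default is the bundled English list."""
    if path is None:
        text = (
            resources.files("topichotspots.data")
            .joinpath("stopwords_en.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return {line.strip().lower() for line in text.splitlines() if line.strip()}


def stopword_hash(words: set[str]) -> str:
    """Stable content hash of a stop list, for provenance headers."""
    joined = "\n".join(sorted(words)).encode("utf-8")
    return hashlib.sha256(joined).hexdigest()[:16]


def preprocess(text: str, stopwords: set[str], min_len: int = 2) -> list[str]:
    """Segment, lowercase, lemmatize and filter one text into tokens.

    Tokens are purely alphabetic, length >= ``min_len``, not in ``stopwords``
    (checked on both surface form and lemma), order preserved.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    tokens = []
    for surface in _TOKEN_RE.findall(text.lower()):
        if surface in stopwords:
            continue
        lemma = lemmatize(surface)
        if len(lemma) >= min_len and lemma not in stopwords:
            tokens.append(lemma)
    return tokens


def preprocess_documents(
    documents: list[Document], stopwords: set[str], min_len: int = 2
) -> list[Document]:
    for doc in documents:
        doc.tokens = preprocess(doc.raw_text, stopwords, min_len)
    return documents


def build_corpus(
    documents: list[Document], min_df: int = 2, year: int | str = "pooled"
) -> Corpus:
    """Build the vocabulary (terms in >= min_df documents) and encode documents.

    Documents emptied by the frequency filter are dropped and counted in
    ``Corpus.n_dropped``. Term ids are assigned in sorted term order so the
    encoding is deterministic.
    """
    df_counter: Counter[str] = Counter()
    for doc in documents:
        df_counter.update(set(doc.tokens))
    terms = sorted(t for t, c in df_counter.items() if c >= min_df)
    vocab = Vocabulary(terms, [df_counter[t] for t in terms])

    kept: list[Document] = []
    dropped = 0
    for doc in documents:
        ids = vocab.encode(doc.tokens)
        if ids:
            doc.token_ids = ids
            kept.append(doc)
        else:
            dropped += 1
    if not kept:
        raise ValueError("empty corpus: no document survived the min_df filter")
    return Corpus(documents=kept, vocabulary=vocab, year=year, n_dropped=dropped)


def count_by_year(documents: list[Document]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for doc in documents:
        counts[doc.year] = counts.get(doc.year, 0) + 1
    return dict(sorted(counts.items()))


def save_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    """Serialize as vocabulary TSV (id, term, df) + documents JSON-lines."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "vocabulary.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\tterm\tdf\n")
        for i, term in enumerate(corpus.vocabulary.terms):
            fh.write(f"{i}\t{term}\t{corpus.vocabulary.df[i]}\n")
    with open(out / "documents.jsonl", "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(
                json.dumps(
                    {"pmid": doc.pmid, "year": doc.year, "token_ids": doc.token_ids}
                )
                + "\n"
            )
    meta = {"year": corpus.year, "M": corpus.M, "V": corpus.V,
            "n_dropped": corpus.n_dropped}
    (out / "corpus.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")


def load_corpus(in_dir: str | Path) -> Corpus:
    src = Path(in_dir)
    terms, df = [], []
    with open(src / "vocabulary.tsv", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            _, term, d = line.rstrip("\n").split("\t")
            terms.append(term)
            df.append(int(d))
    vocab = Vocabulary(terms, df)
    documents = []
    with open(src / "documents.jsonl", encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            ids = rec["token_ids"]
            documents.append(
                Document(
                    pmid=rec["pmid"],
                    year=rec["year"],
                    raw_text="",
                    tokens=vocab.decode(ids),
                    token_ids=ids,
                )
            )
    meta = json.loads((src / "corpus.json").read_text(encoding="utf-8"))
    return Corpus(documents=documents, vocabulary=vocab, year=meta["year"],
                  n_dropped=meta.get("n_dropped", 0))
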
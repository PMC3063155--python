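"""Corpus construction: documents, bio-term dictionaries and extraction.

A *bio-term* is a controlled-vocabulary biological entity — compound, drug,
gene, disease, side-effect or pathway — located in free text by dictionary
matching. Each admitted document carries its journal label, its stemmed and
stopword-filtered token sequence, and the set of bio-terms found in it
(the bio-term vector ``b_d`` that conditions topic assignment during
modelling). Documents with no bio-term, or with too few tokens, are
excluded from training: the generative model draws every token's bio-term
uniformly from ``b_d`` and therefore cannot explain a document with an
empty vector.

On-disk formats are deliberately plain: dictionaries are 3-column TSV
(surface form, canonical id, type), documents arrive as JSON-lines, and a
built corpus round-trips through a directory of TSV id tables plus a
JSON-lines file of encoded documents.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .stem import porter_stem

logger = logging.getLogger(__name__)

#: the six bio-term types
TERM_TYPES = ("compound", "drug", "gene", "disease", "side_effect", "pathway")

#: types included in corpus building unless the caller overrides
DEFAULT_ENABLED_TYPES = frozenset({"drug", "gene", "disease"})

#: surface forms at or below this length require an exact-case match,
#: so that short gene symbols (e.g. "APC") do not fire on common words.
SHORT_FORM_LEN = 3

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


class DictionaryFormatError(ValueError):
    """A dictionary row is malformed or carries an unknown term type."""


@dataclass(frozen=True)
class DictEntry:
    canonical_id: str
    term_type: str
    surface: str  # original (case-preserved) surface form


@dataclass
class BioTermDictionary:
    """Mapping from normalized surface forms to canonical bio-term entries.

    Keys are tuples of case-folded, whitespace-split tokens of the surface
    form; multi-word forms therefore match multi-token spans of text.
    """

    entries: dict[tuple[str, ...], DictEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def max_phrase_len(self) -> int:
        return max((len(k) for k in self.entries), default=0)

    def lookup(self, surface: str) -> DictEntry | None:
        return self.entries.get(_normalize_surface(surface))


def _normalize_surface(surface: str) -> tuple[str, ...]:
    return tuple(surface.casefold().split())


def load_dictionary(path: str | Path) -> BioTermDictionary:
    """Read a 3-column TSV (surface_form, canonical_id, term_type).

    Surface forms are case-folded and whitespace-collapsed; a duplicate
    surface form keeps its first occurrence and logs a warning. Raises
    :class:`DictionaryFormatError` for malformed rows or unknown types,
    naming the offending line number.
    """
    d = BioTermDictionary()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise DictionaryFormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(cols)}"
                )
            surface, canonical_id, term_type = (c.strip() for c in cols)
            if term_type not in TERM_TYPES:
                raise DictionaryFormatError(
                    f"{path}: line {lineno}: unknown term_type {term_type!r} "
                    f"(expected one of {', '.join(TERM_TYPES)})"
                )
            if not surface or not canonical_id:
                raise DictionaryFormatError(
                    f"{path}: line {lineno}: empty surface form or canonical id"
                )
            key = _normalize_surface(surface)
            if key in d.entries:
                logger.warning(
                    "%s: line %d: duplicate surface form %r ignored "
                    "(first occurrence kept)", path, lineno, surface,
                )
                continue
            d.entries[key] = DictEntry(canonical_id, term_type, " ".join(surface.split()))
    return d


def tokenize_and_stem(text: str, stopwords: Iterable[str] | None = None) -> list[str]:
    """Lowercase, strip punctuation, drop stopwords, Porter-stem; order kept.

    ``stopwords=None`` selects the built-in English stop-word list.
    """
    if stopwords is None:
        stopwords = ENGLISH_STOP_WORDS
    stopset = stopwords if isinstance(stopwords, (set, frozenset)) else set(stopwords)
    out = []
    for tok in _TOKEN_RE.findall(text.lower()):
        if tok in stopset:
            continue
        out.append(porter_stem(tok))
    return out


def extract_bioterms(
    text: str,
    dictionaries: Sequence[BioTermDictionary],
    *,
    enabled_types: frozenset[str] | None = None,
) -> set[tuple[str, str]]:
    """Dictionary-match bio-terms in raw (unstemmed) text.

    Scans the word-token sequence left to right; at each position the
    longest matching span wins (so "fatty liver" beats "liver") and the
    scan resumes after it. Matching is case-insensitive except that
    surface forms of length <= SHORT_FORM_LEN characters must match
    exactly, limiting false positives from short gene symbols.

    Returns the set of matched ``(canonical_id, term_type)`` pairs.
    """
    if not dictionaries:
        raise ValueError("at least one dictionary is required")
    if enabled_types is None:
        enabled_types = frozenset(TERM_TYPES)
    raw_tokens = _TOKEN_RE.findall(text)
    folded = [t.casefold() for t in raw_tokens]
    max_len = max(d.max_phrase_len for d in dictionaries)
    found: set[tuple[str, str]] = set()
    i = 0
    n = len(raw_tokens)
    while i < n:
        matched_span = 0
        matched_entry: DictEntry | None = None
        for span in range(min(max_len, n - i), 0, -1):
            key = tuple(folded[i : i + span])
            for d in dictionaries:
                entry = d.entries.get(key)
                if entry is None:
                    continue
                if len(entry.surface) <= SHORT_FORM_LEN:
                    if " ".join(raw_tokens[i : i + span]) != entry.surface:
                        continue
                if entry.term_type not in enabled_types:
                    continue
                matched_span, matched_entry = span, entry
                break
            if matched_entry is not None:
                break
        if matched_entry is not None:
            found.add((matched_entry.canonical_id, matched_entry.term_type))
            i += matched_span
        else:
            i += 1
    return found


@dataclass
class Document:
    """One abstract: journal label, encoded tokens and bio-term vector."""

    doc_id: str
    journal_id: int
    tokens: np.ndarray  # int32 word ids, in text order
    bioterms: np.ndarray  # int32 bio-term ids, sorted unique (b_d)

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.int32)
        self.bioterms = np.asarray(np.unique(self.bioterms), dtype=np.int32)


@dataclass
class Corpus:
    """Indexed document collection with bijective id tables.

    ``vocabulary[w]`` is the word string for word id ``w``; ``bioterms[b]``
    is the ``(canonical_id, term_type)`` pair for bio-term id ``b``;
    ``journals[j]`` the journal name for journal id ``j``.
    """

    documents: list[Document]
    vocabulary: list[str]
    bioterms: list[tuple[str, str]]
    journals: list[str]

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    @property
    def n_bioterms(self) -> int:
        return len(self.bioterms)

    @property
    def n_journals(self) -> int:
        return len(self.journals)

    @property
    def n_tokens(self) -> int:
        return sum(len(d.tokens) for d in self.documents)

    def bioterm_index(self) -> dict[str, int]:
        """canonical id -> bio-term id."""
        return {cid: i for i, (cid, _t) in enumerate(self.bioterms)}

    def validate(self) -> None:
        V, B, J = self.n_words, self.n_bioterms, self.n_journals
        if len(set(self.vocabulary)) != V:
            raise ValueError("vocabulary table is not bijective")
        if len({cid for cid, _ in self.bioterms}) != B:
            raise ValueError("bioterm table is not bijective")
        if len(set(self.journals)) != J:
            raise ValueError("journal table is not bijective")
        for d in self.documents:
            if len(d.tokens) == 0:
                raise ValueError(f"document {d.doc_id} has no tokens")
            if len(d.bioterms) == 0:
                raise ValueError(f"document {d.doc_id} has empty bio-term vector")
            if d.tokens.max(initial=-1) >= V or d.tokens.min(initial=0) < 0:
                raise ValueError(f"document {d.doc_id} has out-of-range word ids")
            if d.bioterms.max(initial=-1) >= B:
                raise ValueError(f"document {d.doc_id} has out-of-range bio-term ids")
            if not 0 <= d.journal_id < J:
                raise ValueError(f"document {d.doc_id} has out-of-range journal id")

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        _write_table(directory / "vocabulary.tsv", self.vocabulary)
        with open(directory / "bioterms.tsv", "w", encoding="utf-8") as fh:
            for i, (cid, ttype) in enumerate(self.bioterms):
                fh.write(f"{i}\t{cid}\t{ttype}\n")
        _write_table(directory / "journals.tsv", self.journals)
        with open(directory / "documents.jsonl", "w", encoding="utf-8") as fh:
            for d in self.documents:
                fh.write(json.dumps({
                    "doc_id": d.doc_id,
                    "journal_id": d.journal_id,
                    "tokens": d.tokens.tolist(),
                    "bioterms": d.bioterms.tolist(),
                }) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "Corpus":
        directory = Path(directory)
        vocabulary = _read_table(directory / "vocabulary.tsv")
        bioterms = []
        with open(directory / "bioterms.tsv", encoding="utf-8") as fh:
            for line in fh:
                _i, cid, ttype = line.rstrip("\n").split("\t")
                bioterms.append((cid, ttype))
        journals = _read_table(directory / "journals.tsv")
        documents = []
        with open(directory / "documents.jsonl", encoding="utf-8") as fh:
            for line in fh:
                rec = json.loads(line)
                documents.append(Document(
                    rec["doc_id"], rec["journal_id"],
                    np.array(rec["tokens"], dtype=np.int32),
                    np.array(rec["bioterms"], dtype=np.int32),
                ))
        c = cls(documents, vocabulary, bioterms, journals)
        c.validate()
        return c


def _write_table(path: Path, items: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, s in enumerate(items):
            fh.write(f"{i}\t{s}\n")


def _read_table(path: Path) -> list[str]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            _i, s = line.rstrip("\n").split("\t", 1)
            out.append(s)
    return out


class _Indexer:
    """Assigns dense ids in first-occurrence order."""

    def __init__(self) -> None:
        self.index: dict = {}
        self.items: list = []

    def __call__(self, item) -> int:
        i = self.index.get(item)
        if i is None:
            i = len(self.items)
            self.index[item] = i
            self.items.append(item)
        return i


def build_corpus(
    raw_docs: Iterable[Mapping],
    dictionaries: Sequence[BioTermDictionary] = (),
    *,
    stopwords: Iterable[str] | None = None,
    min_doc_tokens: int = 1,
    enabled_types: frozenset[str] = DEFAULT_ENABLED_TYPES,
) -> Corpus:
    """Assemble an indexed :class:`Corpus` from JSON-record documents.

    Each record needs ``doc_id``, ``journal`` and ``text``; an optional
    ``bioterms`` list of ``[canonical_id, term_type]`` pairs overrides
    dictionary extraction for that record. Documents whose bio-term vector
    is empty, or with fewer than ``min_doc_tokens`` tokens, are excluded
    (count logged). Id tables are assigned in first-occurrence order, so
    the same input always yields the same corpus.
    """
    word_ix, bt_ix, j_ix = _Indexer(), _Indexer(), _Indexer()
    documents: list[Document] = []
    n_excluded = 0
    for rec in raw_docs:
        tokens = tokenize_and_stem(rec["text"], stopwords)
        if "bioterms" in rec and rec["bioterms"] is not None:
            terms = {(cid, ttype) for cid, ttype in rec["bioterms"]
                     if ttype in enabled_types}
        elif dictionaries:
            terms = extract_bioterms(rec["text"], dictionaries,
                                     enabled_types=enabled_types)
        else:
            terms = set()
        if len(tokens) < min_doc_tokens or not terms:
            n_excluded += 1
            continue
        documents.append(Document(
            str(rec["doc_id"]),
            j_ix(rec["journal"]),
            np.array([word_ix(t) for t in tokens], dtype=np.int32),
            np.array(sorted(bt_ix(t) for t in sorted(terms)), dtype=np.int32),
        ))
    if n_excluded:
        logger.info("build_corpus: excluded %d document(s) "
                    "(empty bio-term vector or too few tokens)", n_excluded)
    if not documents:
        raise ValueError("no admissible documents: every record was excluded")
    corpus = Corpus(documents, word_ix.items, bt_ix.items, j_ix.items)
    corpus.validate()
    return corpus


def read_jsonl(path: str | Path) -> list[dict]:
    """Read a JSON-lines document file."""
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]
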
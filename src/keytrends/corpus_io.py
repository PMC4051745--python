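"""Reading, tokenizing, and windowing dated multi-stream document corpora.

A corpus is a collection of documents, each tagged with a stream label (for
example ``"newspaper"`` or ``"web"``) and a calendar month. Text is reduced
to sentences of tokens by a configurable delimiter-based tokenizer; for
languages without delimiter-separated words (the motivating corpora are
Japanese) a pre-segmented text or an external tokenizer producing
space-separated tokens is expected upstream.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, replace

from .months import month_index, parse_month

logger = logging.getLogger(__name__)

DEFAULT_SENTENCE_DELIMITERS = ".!?\n。！？"
DEFAULT_TOKEN_DELIMITERS = " \t\r,;:\"'()[]{}<>/\\|、"


@dataclass(frozen=True)
class TokenizerConfig:
    """Delimiter-based tokenizer settings.

    Sentences are split on any character in ``sentence_delimiters``, tokens
    on any character in ``token_delimiters``. Tokens are optionally
    lowercased, then stopwords and tokens shorter than ``min_token_length``
    are removed; sentences left empty are dropped.
    """

    lowercase: bool = True
    sentence_delimiters: str = DEFAULT_SENTENCE_DELIMITERS
    token_delimiters: str = DEFAULT_TOKEN_DELIMITERS
    stopwords: frozenset[str] = frozenset()
    min_token_length: int = 1

    def __post_init__(self) -> None:
        if not self.sentence_delimiters or not self.token_delimiters:
            raise ValueError("delimiter sets must be non-empty")
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")


@dataclass(frozen=True)
class Document:
    """One dated article or page: an ordered list of token sentences."""

    doc_id: str
    stream: str
    month: str  # "YYYY-MM"
    sentences: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        month_index(self.month)  # validates
        for s in self.sentences:
            if not s or any(not t for t in s):
                raise ValueError(f"document {self.doc_id!r} has an empty sentence/token")


@dataclass(frozen=True)
class Corpus:
    """An immutable set of documents with an inclusive month window."""

    documents: tuple[Document, ...]
    window: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for d in self.documents:
            if d.doc_id in seen:
                raise ValueError(f"duplicate doc_id {d.doc_id!r}")
            seen.add(d.doc_id)
        if self.window is None and self.documents:
            months = sorted(self.documents, key=lambda d: month_index(d.month))
            object.__setattr__(self, "window", (months[0].month, months[-1].month))
        if self.window is not None:
            lo, hi = month_index(self.window[0]), month_index(self.window[1])
            if lo > hi:
                raise ValueError("window start after end")
            for d in self.documents:
                if not lo <= month_index(d.month) <= hi:
                    raise ValueError(
                        f"document {d.doc_id!r} month {d.month} outside window {self.window}"
                    )

    @property
    def streams(self) -> set[str]:
        return {d.stream for d in self.documents}

    def __len__(self) -> int:
        return len(self.documents)


def tokenize(text: str, config: TokenizerConfig | None = None) -> list[list[str]]:
    """Split text into sentences of tokens according to ``config``.

    Deterministic; empty input yields an empty list.
    """
    config = config or TokenizerConfig()
    if not text:
        return []
    sent_re = re.compile("[" + re.escape(config.sentence_delimiters) + "]")
    tok_re = re.compile("[" + re.escape(config.token_delimiters) + "]")
    sentences: list[list[str]] = []
    for raw in sent_re.split(text):
        tokens = []
        for tok in tok_re.split(raw):
            if config.lowercase:
                tok = tok.lower()
            if len(tok) < config.min_token_length or tok in config.stopwords:
                continue
            tokens.append(tok)
        if tokens:
            sentences.append(tokens)
    return sentences


def _record_to_document(
    record: dict, where: str, tokenizer: TokenizerConfig
) -> Document:
    for key in ("id", "stream", "date", "text"):
        if key not in record or record[key] is None:
            raise ValueError(f"{where}: missing field {key!r}")
    month = parse_month(str(record["date"]))
    sentences = tuple(tuple(s) for s in tokenize(str(record["text"]), tokenizer))
    if not sentences:
        logger.info("%s: document %r empty after tokenization", where, record["id"])
    return Document(str(record["id"]), str(record["stream"]), month, sentences)


def read_corpus(
    path: str,
    format: str | None = None,
    tokenizer: TokenizerConfig | None = None,
) -> Corpus:
    """Read a JSONL or CSV corpus file into a tokenized :class:`Corpus`.

    Each record needs ``id``, ``stream``, ``date`` and ``text`` fields; the
    date is truncated to its calendar month. Documents that tokenize to
    nothing are kept (with zero sentences) so they still count as documents.
    Malformed records and duplicate ids raise with the offending line noted.
    """
    tokenizer = tokenizer or TokenizerConfig()
    if format is None:
        format = "csv" if str(path).lower().endswith(".csv") else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown corpus format {format!r}")

    docs: list[Document] = []
    first_line: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        if format == "jsonl":
            records = (
                (f"line {i}", line)
                for i, line in enumerate(fh, start=1)
                if line.strip()
            )
            for where, line in records:
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}: {where}: invalid JSON ({exc})") from exc
                docs.append(_make_doc(record, path, where, tokenizer, first_line))
        else:
            reader = csv.DictReader(fh)
            for i, record in enumerate(reader, start=2):  # header is line 1
                docs.append(_make_doc(record, path, f"line {i}", tokenizer, first_line))
    return Corpus(tuple(docs))


def _make_doc(record, path, where, tokenizer, first_line) -> Document:
    try:
        doc = _record_to_document(record, where, tokenizer)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if doc.doc_id in first_line:
        raise ValueError(
            f"{path}: duplicate doc_id {doc.doc_id!r} at {first_line[doc.doc_id]} and {where}"
        )
    first_line[doc.doc_id] = where
    return doc


def write_corpus(corpus: Corpus, path: str) -> None:
    """Write a corpus as JSONL, rebuilding text from tokens.

    Sentences are joined with ". " and tokens with spaces, so reading the
    file back with the default tokenizer round-trips ids, streams, months
    and token content exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            text = ". ".join(" ".join(s) for s in d.sentences)
            fh.write(
                json.dumps(
                    {"id": d.doc_id, "stream": d.stream, "date": d.month, "text": text},
                    ensure_ascii=False,
                )
                + "\n"
            )


def filter_window(corpus: Corpus, start: str, end: str) -> Corpus:
    """Restrict a corpus to months in [start, end] inclusive (non-mutating)."""
    lo, hi = month_index(parse_month(start)), month_index(parse_month(end))
    if lo > hi:
        raise ValueError(f"window start {start!r} after end {end!r}")
    docs = tuple(d for d in corpus.documents if lo <= month_index(d.month) <= hi)
    return Corpus(docs, window=(parse_month(start), parse_month(end)))


def load_stopwords(path: str) -> frozenset[str]:
    """Read a stopword list, one token per line; blank lines ignored."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def corpus_with_window(corpus: Corpus, window: tuple[str, str]) -> Corpus:
    """Return the same documents under an explicit (possibly wider) window."""
    return replace(corpus, window=window)
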
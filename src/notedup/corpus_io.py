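"""Corpus containers and I/O.

A corpus is an ordered collection of free-text documents (clinical notes,
newswire articles, ...) with optional metadata: a patient identifier, a
date and a note type.  Text is kept line-structured because both the
fingerprinting scheme and bigram counting operate within lines, never
across them.  An optional flat "concept" token layer per document stands
in for terminology-normalized annotations (e.g. UMLS CUIs); all concept
analyses here are count-based, so no offsets are stored.
"""

from __future__ import annotations

import csv
import datetime
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TokenizerConfig",
    "Document",
    "Corpus",
    "tokenize",
    "read_corpus",
    "write_corpus",
]


@dataclass(frozen=True)
class TokenizerConfig:
    """Deterministic tokenizer settings.

    lowercase
        Fold everything to lower case (default on).
    split_punctuation
        Detach punctuation marks into their own tokens (default on).
    keep_numbers
        Keep purely numeric tokens; alphanumerics like ``10mg`` are always
        kept (default on).
    """

    lowercase: bool = True
    split_punctuation: bool = True
    keep_numbers: bool = True


_SPLIT_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)
_PURE_NUMBER_RE = re.compile(r"^\d+([.,]\d+)*$")


def tokenize(text: str, config: TokenizerConfig = TokenizerConfig()) -> list[str]:
    """Tokenize one line of text.

    Whitespace-delimited; punctuation is split into separate tokens when
    ``split_punctuation`` is set.  Deterministic, and idempotent on its own
    output joined by single spaces.  Empty text yields an empty list.
    """
    if config.lowercase:
        text = text.lower()
    if config.split_punctuation:
        tokens = _SPLIT_RE.findall(text)
    else:
        tokens = text.split()
    if not config.keep_numbers:
        tokens = [t for t in tokens if not _PURE_NUMBER_RE.match(t)]
    return tokens


@dataclass
class Document:
    """One note: line-structured text plus optional metadata.

    ``token_lines`` parallels ``raw_lines`` (one token list per raw line;
    blank lines are kept as empty token lines).  ``concept_tokens`` is an
    optional flat sequence of concept identifiers.
    """

    doc_id: str
    raw_lines: list[str]
    token_lines: list[list[str]]
    patient_id: str | None = None
    date: datetime.date | None = None
    note_type: str | None = None
    concept_tokens: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.raw_lines) != len(self.token_lines):
            raise ValueError(
                f"document {self.doc_id!r}: raw_lines and token_lines "
                f"lengths differ ({len(self.raw_lines)} vs {len(self.token_lines)})"
            )

    @classmethod
    def from_text(
        cls,
        doc_id: str,
        text: str,
        tokenizer: TokenizerConfig = TokenizerConfig(),
        **metadata,
    ) -> "Document":
        """Build a document by splitting ``text`` on newlines and tokenizing."""
        raw_lines = text.split("\n")
        token_lines = [tokenize(line, tokenizer) for line in raw_lines]
        return cls(doc_id, raw_lines, token_lines, **metadata)

    def tokens(self, layer: str = "word") -> list[str]:
        """Flattened token stream for the requested layer."""
        if layer == "word":
            return [t for line in self.token_lines for t in line]
        if layer == "concept":
            if self.concept_tokens is None:
                raise ValueError(
                    f"document {self.doc_id!r} has no concept layer"
                )
            return list(self.concept_tokens)
        raise ValueError(f"unknown layer {layer!r}")

    @property
    def text(self) -> str:
        return "\n".join(self.raw_lines)

    def n_tokens(self, layer: str = "word") -> int:
        return len(self.tokens(layer))


class Corpus:
    """Ordered collection of :class:`Document` with a selected token layer.

    Iteration order is stable and equals insertion order.  ``layer`` selects
    which token stream (``word`` or ``concept``) count-based analyses use;
    selecting ``concept`` on documents lacking a concept layer raises when
    those tokens are requested.
    """

    def __init__(self, documents: Iterable[Document] = (), layer: str = "word"):
        if layer not in ("word", "concept"):
            raise ValueError(f"unknown layer {layer!r}")
        self.layer = layer
        self._docs: list[Document] = []
        self._index: dict[str, int] = {}
        for doc in documents:
            self.add(doc)

    def add(self, doc: Document) -> None:
        if doc.doc_id in self._index:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        self._index[doc.doc_id] = len(self._docs)
        self._docs.append(doc)

    def __len__(self) -> int:
        return len(self._docs)

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._index

    def __getitem__(self, key) -> Document:
        if isinstance(key, int):
            return self._docs[key]
        return self._docs[self._index[key]]

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self._docs]

    def doc_tokens(self, doc: Document) -> list[str]:
        """Flat token stream of ``doc`` under this corpus's layer."""
        return doc.tokens(self.layer)

    def doc_token_lines(self, doc: Document) -> list[list[str]]:
        """Token lines of ``doc`` under this corpus's layer.

        The concept layer is flat, so it is exposed as a single line.
        """
        if self.layer == "word":
            return doc.token_lines
        return [doc.tokens("concept")]

    def patients(self) -> dict[str, list[Document]]:
        """Documents grouped by patient_id (documents without one excluded)."""
        groups: dict[str, list[Document]] = {}
        for doc in self._docs:
            if doc.patient_id is not None:
                groups.setdefault(doc.patient_id, []).append(doc)
        return groups

    def subset(self, doc_ids: Sequence[str]) -> "Corpus":
        """New corpus holding the named documents, in the given order."""
        return Corpus((self[i] for i in doc_ids), layer=self.layer)

    def with_layer(self, layer: str) -> "Corpus":
        sub = Corpus(layer=layer)
        sub._docs = self._docs
        sub._index = self._index
        return sub

    def total_tokens(self) -> int:
        return sum(len(self.doc_tokens(d)) for d in self._docs)


def _parse_date(value: str | None, doc_id: str) -> datetime.date | None:
    if value is None or value == "":
        return None
    try:
        return datetime.date.fromisoformat(value)
    except ValueError as exc:
        raise ValueError(f"document {doc_id!r}: bad date {value!r}") from exc


def read_corpus(
    path: str | Path,
    format: str = "jsonl",
    tokenizer: TokenizerConfig = TokenizerConfig(),
) -> Corpus:
    """Read a corpus from JSONL or a directory of text files.

    JSONL: one object per line with keys ``doc_id``, ``text`` and optional
    ``patient_id``, ``date`` (ISO-8601), ``note_type``, ``concepts``.
    textdir: one ``.txt`` file per document (doc_id = filename stem), files
    in sorted-name order, plus an optional ``metadata.tsv`` with columns
    doc_id, patient_id, date, note_type.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    corpus = Corpus()
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed JSON") from exc
                if "doc_id" not in record or "text" not in record:
                    raise ValueError(
                        f"{path}:{lineno}: record must contain doc_id and text"
                    )
                doc_id = str(record["doc_id"])
                concepts = record.get("concepts")
                doc = Document.from_text(
                    doc_id,
                    record["text"],
                    tokenizer,
                    patient_id=record.get("patient_id"),
                    date=_parse_date(record.get("date"), doc_id),
                    note_type=record.get("note_type"),
                    concept_tokens=list(concepts) if concepts is not None else None,
                )
                corpus.add(doc)
    elif format == "textdir":
        meta: dict[str, dict] = {}
        meta_path = path / "metadata.tsv"
        if meta_path.exists():
            with meta_path.open(encoding="utf-8", newline="") as fh:
                for row in csv.DictReader(fh, delimiter="\t"):
                    meta[row["doc_id"]] = row
        for txt in sorted(path.glob("*.txt")):
            doc_id = txt.stem
            row = meta.get(doc_id, {})
            doc = Document.from_text(
                doc_id,
                txt.read_text(encoding="utf-8"),
                tokenizer,
                patient_id=row.get("patient_id") or None,
                date=_parse_date(row.get("date"), doc_id),
                note_type=row.get("note_type") or None,
            )
            corpus.add(doc)
    else:
        raise ValueError(f"unknown format {format!r}")
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL (the round-trippable format)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in corpus:
            record: dict = {"doc_id": doc.doc_id, "text": doc.text}
            if doc.patient_id is not None:
                record["patient_id"] = doc.patient_id
            if doc.date is not None:
                record["date"] = doc.date.isoformat()
            if doc.note_type is not None:
                record["note_type"] = doc.note_type
            if doc.concept_tokens is not None:
                record["concepts"] = doc.concept_tokens
            fh.write(json.dumps(record) + "\n")
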
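"""Prescription data model, vocabularies, and corpus readers/writers.

A prescription is a short two-view document: a handful of diagnosis terms
(view A) and a handful of medication terms (view B). Corpora are stored as
JSON Lines (canonical) or CSV with ``|``-joined multi-valued cells.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PrescriptionRecord",
    "Vocabulary",
    "EncodedCorpus",
    "CorpusFormatError",
    "normalize_term",
    "encode_records",
    "read_corpus",
    "write_corpus",
]

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Trim and collapse internal whitespace. No coding-system normalization:
    terms (generic drug names, diagnosis names) are matched as recorded."""
    return _WS.sub(" ", term.strip())


class CorpusFormatError(ValueError):
    """Malformed corpus file (bad line, duplicate ID, unknown format)."""


@dataclass
class PrescriptionRecord:
    """One prescription: diagnosis tokens (view A) and medication tokens
    (view B), plus an optional ground-truth label (1 = inappropriate)."""

    prescription_id: str
    diagnoses: list[str] = field(default_factory=list)
    medications: list[str] = field(default_factory=list)
    label: int | None = None

    def normalized(self) -> "PrescriptionRecord":
        return PrescriptionRecord(
            prescription_id=self.prescription_id,
            diagnoses=[normalize_term(t) for t in self.diagnoses],
            medications=[normalize_term(t) for t in self.medications],
            label=self.label,
        )


class Vocabulary:
    """Bijective term<->index map for one view, indices assigned in
    first-appearance order."""

    def __init__(self, view: str, terms: Iterable[str] = ()):  # view in {"A","B"}
        if view not in ("A", "B"):
            raise ValueError(f"view must be 'A' or 'B', got {view!r}")
        self.view = view
        self._index: dict[str, int] = {}
        self._terms: list[str] = []
        for t in terms:
            self.add(t)

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self._index

    @property
    def terms(self) -> list[str]:
        return list(self._terms)

    def add(self, term: str) -> int:
        term = normalize_term(term)
        idx = self._index.get(term)
        if idx is None:
            idx = len(self._terms)
            self._index[term] = idx
            self._terms.append(term)
        return idx

    def index(self, term: str) -> int:
        """Index of a term; KeyError if out of vocabulary."""
        return self._index[normalize_term(term)]

    def get(self, term: str) -> int | None:
        return self._index.get(normalize_term(term))

    def term(self, index: int) -> str:
        return self._terms[index]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Vocabulary)
            and self.view == other.view
            and self._terms == other._terms
        )


@dataclass
class EncodedCorpus:
    """Integer-encoded two-view corpus in flat (tokens, offsets) layout.

    Document ``m`` of view A is ``tokens_A[offsets_A[m]:offsets_A[m+1]]``.
    ``labels`` is None for unlabeled corpora; ``n_dropped`` counts records
    excluded at read time because both views were empty.
    """

    ids: list[str]
    tokens_A: np.ndarray
    offsets_A: np.ndarray
    tokens_B: np.ndarray
    offsets_B: np.ndarray
    vocab_A: Vocabulary
    vocab_B: Vocabulary
    labels: np.ndarray | None = None
    n_dropped: int = 0

    @property
    def M(self) -> int:
        return len(self.ids)

    def doc_A(self, m: int) -> np.ndarray:
        return self.tokens_A[self.offsets_A[m] : self.offsets_A[m + 1]]

    def doc_B(self, m: int) -> np.ndarray:
        return self.tokens_B[self.offsets_B[m] : self.offsets_B[m + 1]]

    def record(self, m: int) -> PrescriptionRecord:
        return PrescriptionRecord(
            prescription_id=self.ids[m],
            diagnoses=[self.vocab_A.term(v) for v in self.doc_A(m)],
            medications=[self.vocab_B.term(v) for v in self.doc_B(m)],
            label=None if self.labels is None else int(self.labels[m]),
        )

    def records(self) -> list[PrescriptionRecord]:
        return [self.record(m) for m in range(self.M)]

    def validate(self) -> None:
        if self.tokens_A.size and self.tokens_A.max() >= len(self.vocab_A):
            raise ValueError("view-A token index exceeds vocabulary size")
        if self.tokens_B.size and self.tokens_B.max() >= len(self.vocab_B):
            raise ValueError("view-B token index exceeds vocabulary size")
        if len(self.offsets_A) != self.M + 1 or len(self.offsets_B) != self.M + 1:
            raise ValueError("offset arrays inconsistent with record count")


def encode_records(
    records: Sequence[PrescriptionRecord],
    vocab_A: Vocabulary | None = None,
    vocab_B: Vocabulary | None = None,
    drop_empty: bool = True,
) -> EncodedCorpus:
    """Encode records against (possibly growing) vocabularies.

    Records with both views empty are dropped and counted, mirroring the
    exclusion of unusable prescriptions during data preparation. Duplicate
    prescription IDs raise :class:`CorpusFormatError`.
    """
    vocab_A = vocab_A if vocab_A is not None else Vocabulary("A")
    vocab_B = vocab_B if vocab_B is not None else Vocabulary("B")
    ids: list[str] = []
    seen: set[str] = set()
    toks_A: list[int] = []
    toks_B: list[int] = []
    offs_A = [0]
    offs_B = [0]
    labels: list[int | None] = []
    n_dropped = 0
    for rec in records:
        rec = rec.normalized()
        if rec.prescription_id in seen:
            raise CorpusFormatError(
                f"duplicate prescription_id {rec.prescription_id!r}"
            )
        seen.add(rec.prescription_id)
        if drop_empty and not rec.diagnoses and not rec.medications:
            n_dropped += 1
            continue
        ids.append(rec.prescription_id)
        toks_A.extend(vocab_A.add(t) for t in rec.diagnoses)
        toks_B.extend(vocab_B.add(t) for t in rec.medications)
        offs_A.append(len(toks_A))
        offs_B.append(len(toks_B))
        labels.append(rec.label)
    has_labels = any(l is not None for l in labels)
    return EncodedCorpus(
        ids=ids,
        tokens_A=np.asarray(toks_A, dtype=np.int32),
        offsets_A=np.asarray(offs_A, dtype=np.int64),
        tokens_B=np.asarray(toks_B, dtype=np.int32),
        offsets_B=np.asarray(offs_B, dtype=np.int64),
        vocab_A=vocab_A,
        vocab_B=vocab_B,
        labels=np.asarray([0 if l is None else int(l) for l in labels], dtype=np.int8)
        if has_labels
        else None,
        n_dropped=n_dropped,
    )


def _record_from_obj(obj: dict, where: str) -> PrescriptionRecord:
    try:
        label = obj.get("label")
        return PrescriptionRecord(
            prescription_id=str(obj["prescription_id"]),
            diagnoses=[str(t) for t in obj.get("diagnoses", [])],
            medications=[str(t) for t in obj.get("medications", [])],
            label=None if label is None else int(label),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusFormatError(f"{where}: malformed record ({exc})") from exc


def iter_jsonl(path: str | Path) -> Iterable[PrescriptionRecord]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            yield _record_from_obj(obj, f"line {lineno}")


def _split_cell(cell: str) -> list[str]:
    return [t for t in (s.strip() for s in cell.split("|")) if t]


def iter_csv(path: str | Path) -> Iterable[PrescriptionRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"prescription_id", "diagnoses", "medications"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CorpusFormatError(
                f"CSV header must contain {sorted(required)}; got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            if row.get("prescription_id") is None:
                raise CorpusFormatError(f"line {lineno}: missing prescription_id")
            label_cell = (row.get("label") or "").strip()
            yield _record_from_obj(
                {
                    "prescription_id": row["prescription_id"],
                    "diagnoses": _split_cell(row.get("diagnoses") or ""),
                    "medications": _split_cell(row.get("medications") or ""),
                    "label": int(label_cell) if label_cell else None,
                },
                f"line {lineno}",
            )


def read_corpus(path: str | Path, format: str = "jsonl") -> EncodedCorpus:
    """Read a corpus file into an :class:`EncodedCorpus`.

    Vocabularies are built from the data in first-appearance order; records
    with both views empty are dropped and reported via ``n_dropped``.
    """
    if format == "jsonl":
        records = list(iter_jsonl(path))
    elif format == "csv":
        records = list(iter_csv(path))
    else:
        raise CorpusFormatError(f"unknown corpus format {format!r}")
    return encode_records(records)


def write_corpus(corpus: EncodedCorpus, path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus; output is bit-stable for a given corpus and readable
    back by :func:`read_corpus`."""
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in corpus.records():
                obj = {
                    "prescription_id": rec.prescription_id,
                    "diagnoses": rec.diagnoses,
                    "medications": rec.medications,
                }
                if rec.label is not None:
                    obj["label"] = rec.label
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["prescription_id", "diagnoses", "medications", "label"])
            for rec in corpus.records():
                writer.writerow(
                    [
                        rec.prescription_id,
                        "|".join(rec.diagnoses),
                        "|".join(rec.medications),
                        "" if rec.label is None else rec.label,
                    ]
                )
    else:
        raise CorpusFormatError(f"unknown corpus format {format!r}")
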
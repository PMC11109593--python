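"""Document construction: sentence segmentation and table linearization.

Tables arrive as structured JSON grids (PDF layout parsing is out of
scope).  Each non-empty data cell is rendered as a "pseudo-sentence" —
``"<row header> : <column header> is <cell> ."`` — so that table content can
pass through the same sequence tagger as body text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .errors import ValidationError

# Abbreviations that must not terminate a sentence.
_ABBREVIATIONS = {
    "al",
    "approx",
    "cf",
    "dr",
    "e.g",
    "eg",
    "et",
    "et al",
    "etc",
    "fig",
    "figs",
    "i.e",
    "ie",
    "mr",
    "mrs",
    "ms",
    "no",
    "prof",
    "ref",
    "resp",
    "sd",
    "vol",
    "vs",
}

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+[A-Z0-9(\[])")
_TRAILING_WORD_RE = re.compile(r"([A-Za-z][A-Za-z.]*)\s*$")


@dataclass
class Table:
    """A rectangular grid of cell strings with header rows/columns."""

    table_id: str
    caption: str
    cells: list[list[str]]
    header_row_count: int = 1
    header_col_count: int = 1

    def __post_init__(self) -> None:
        if self.cells:
            widths = {len(row) for row in self.cells}
            if len(widths) != 1:
                raise ValidationError(
                    f"table {self.table_id}: grid is not rectangular"
                )
        n_rows = len(self.cells)
        n_cols = len(self.cells[0]) if self.cells else 0
        if n_rows and self.header_row_count >= n_rows:
            raise ValidationError(
                f"table {self.table_id}: header_row_count {self.header_row_count} "
                f">= row count {n_rows}"
            )
        if n_cols and self.header_col_count >= n_cols:
            raise ValidationError(
                f"table {self.table_id}: header_col_count {self.header_col_count} "
                f">= column count {n_cols}"
            )


@dataclass
class PseudoSentence:
    """A templated sentence synthesized from one table cell."""

    text: str
    table_id: str
    row: int
    col: int


@dataclass
class Document:
    doc_id: str
    body_text: str
    sentences: list[tuple[int, int]] = field(default_factory=list)
    tables: list[Table] = field(default_factory=list)
    pseudo_sentences: list[PseudoSentence] = field(default_factory=list)


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans (0-based, half-open offsets).

    Splits occur after sentence-final punctuation followed by whitespace and
    an uppercase letter (or digit/bracket), except after known
    abbreviations.  Segmentation is lossless: every non-whitespace character
    belongs to exactly one sentence.
    """
    if not text.strip():
        return []
    breakpoints = []
    for match in _BOUNDARY_RE.finditer(text):
        prefix = text[: match.start()]
        word = _TRAILING_WORD_RE.search(prefix)
        if word and word.group(1).rstrip(".").lower() in _ABBREVIATIONS:
            continue
        breakpoints.append(match.end())
    spans = []
    start = 0
    for bp in breakpoints + [len(text)]:
        chunk = text[start:bp]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((start + lead, bp - trail))
        start = bp
    return spans


def linearize_table(table: Table) -> list[PseudoSentence]:
    """Render each non-empty data cell as a pseudo-sentence.

    Multi-level headers are joined with " , ".  Empty cells are skipped.
    Provenance (table id, row, column) is recorded per pseudo-sentence.
    """
    out: list[PseudoSentence] = []
    hr, hc = table.header_row_count, table.header_col_count
    for r in range(hr, len(table.cells)):
        row = table.cells[r]
        row_header = " , ".join(
            cell.strip() for cell in row[:hc] if cell.strip()
        )
        for c in range(hc, len(row)):
            cell = row[c].strip()
            if not cell:
                continue
            col_header = " , ".join(
                table.cells[i][c].strip()
                for i in range(hr)
                if table.cells[i][c].strip()
            )
            out.append(
                PseudoSentence(
                    text=f"{row_header} : {col_header} is {cell} .",
                    table_id=table.table_id,
                    row=r,
                    col=c,
                )
            )
    return out


def build_document(
    doc_id: str, text: str, tables: Sequence[Table] = ()
) -> Document:
    """Assemble a :class:`Document` with sentences and pseudo-sentences."""
    ids = [t.table_id for t in tables]
    if len(ids) != len(set(ids)):
        raise ValidationError(f"{doc_id}: duplicate table ids")
    doc = Document(doc_id=doc_id, body_text=text, tables=list(tables))
    doc.sentences = segment_sentences(text)
    for table in tables:
        doc.pseudo_sentences.extend(linearize_table(table))
    return doc


def document_from_dict(obj: dict) -> Document:
    tables = [
        Table(
            table_id=t["table_id"],
            caption=t.get("caption", ""),
            cells=t["cells"],
            header_row_count=t.get("header_row_count", 1),
            header_col_count=t.get("header_col_count", 1),
        )
        for t in obj.get("tables", [])
    ]
    return build_document(obj["doc_id"], obj.get("text", ""), tables)


def document_to_dict(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "text": doc.body_text,
        "tables": [
            {
                "table_id": t.table_id,
                "caption": t.caption,
                "cells": t.cells,
                "header_row_count": t.header_row_count,
                "header_col_count": t.header_col_count,
            }
            for t in doc.tables
        ],
    }


def write_documents(docs: Sequence[Document], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(document_to_dict(doc), ensure_ascii=False))
            fh.write("\n")


def read_documents(path: str | Path) -> list[Document]:
    """Read JSON-lines documents ({doc_id, text, tables})."""
    docs = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(document_from_dict(json.loads(line)))
    return docs
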
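"""Core data model: documents, typed entity spans, tokenization, BIO conversion, I/O.

Offsets are 0-based, half-open, character-level throughout. Flat NER only:
entities never overlap and never nest. "Token boundary" equality for exact
matching is realized as character-offset equality under the shared tokenizer,
which is consistent because both gold and parsed spans are snapped to token
boundaries.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

Token = tuple[str, int, int]

# Alphanumeric runs are single tokens; every other non-space character is its
# own token. Underscore is treated as punctuation.
_TOKEN_RE = re.compile(r"[^\W_]+|[^\s\w]|_", re.UNICODE)

# Sentence-final punctuation followed by whitespace ends a sentence.
_SENT_END_RE = re.compile(r"[.!?]+(?=\s)")


class CorpusError(ValueError):
    """Invalid document, entity, or corpus construction."""


class BioTagError(ValueError):
    """Invalid BIO tag or tag transition; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


def tokenize(text: str) -> list[Token]:
    """Split *text* into (surface, start, end) tokens.

    The token offsets partition the non-whitespace content of the input:
    re-inserting the skipped gaps reconstructs the text exactly.
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans (start, end) with global character offsets.

    Splits on newlines first, then after sentence-final punctuation followed
    by whitespace. Leading/trailing whitespace is excluded from each span.
    """
    spans: list[tuple[int, int]] = []
    line_start = 0
    for line in text.split("\n"):
        line_end = line_start + len(line)
        cursor = line_start
        for m in _SENT_END_RE.finditer(text, line_start, line_end):
            spans.append((cursor, m.end()))
            cursor = m.end()
        if cursor < line_end:
            spans.append((cursor, line_end))
        line_start = line_end + 1
    out = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            out.append((s, e))
    return out


@dataclass(frozen=True, order=True)
class Entity:
    """A typed character span [start, end) within one document's text."""

    start: int
    end: int
    label: str
    text: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"invalid entity span [{self.start}, {self.end}): "
                "need 0 <= start < end"
            )

    def overlaps(self, other: "Entity") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Document:
    """Raw text plus its gold entities (sorted, non-overlapping)."""

    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)

    def __post_init__(self) -> None:
        ents = sorted(self.entities)
        for e in ents:
            if e.end > len(self.text):
                raise CorpusError(
                    f"{self.doc_id}: entity [{e.start},{e.end}) exceeds "
                    f"text length {len(self.text)}"
                )
            covered = self.text[e.start : e.end]
            if e.text and e.text != covered:
                raise CorpusError(
                    f"{self.doc_id}: entity text {e.text!r} does not match "
                    f"document substring {covered!r} at [{e.start},{e.end})"
                )
            if not e.text:
                object.__setattr__(e, "text", covered)
        for a, b in zip(ents, ents[1:]):
            if a.overlaps(b):
                raise CorpusError(
                    f"{self.doc_id}: overlapping entities "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        self.entities = ents

    def sentences(self) -> list["Document"]:
        """Sentence sub-documents with localized entity offsets.

        Entities crossing a sentence boundary are kept with the sentence
        containing their start (offsets clipped are NOT allowed; such
        entities are dropped with a warning — they do not occur in
        well-formed flat corpora).
        """
        subs = []
        for i, (s, e) in enumerate(segment_sentences(self.text)):
            ents = []
            for ent in self.entities:
                if ent.start >= s and ent.end <= e:
                    ents.append(
                        Entity(ent.start - s, ent.end - s, ent.label, ent.text)
                    )
                elif ent.start < e and ent.end > s and not (ent.start >= s):
                    logger.warning(
                        "%s: entity [%d,%d) crosses sentence boundary; dropped "
                        "from sentence view",
                        self.doc_id,
                        ent.start,
                        ent.end,
                    )
            subs.append(Document(f"{self.doc_id}#s{i}", self.text[s:e], ents))
        return subs


@dataclass
class Corpus:
    """A list of documents, an ordered label inventory, and split tags."""

    documents: list[Document]
    labels: list[str]
    split: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for d in self.documents:
            if d.doc_id in seen:
                raise CorpusError(f"duplicate doc_id {d.doc_id!r}")
            seen.add(d.doc_id)
            for e in d.entities:
                if e.label not in self.labels:
                    raise CorpusError(
                        f"{d.doc_id}: label {e.label!r} not in corpus "
                        f"inventory {self.labels}"
                    )
        for doc_id, tag in self.split.items():
            if tag not in ("train", "valid", "test"):
                raise CorpusError(f"invalid split tag {tag!r} for {doc_id!r}")

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def docs_in_split(self, tag: str) -> list[Document]:
        return [d for d in self.documents if self.split.get(d.doc_id) == tag]

    def __getitem__(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)


@dataclass
class TokenizedDocument:
    """Tokens with 1:1 aligned BIO tags."""

    tokens: list[Token]
    bio_tags: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.bio_tags):
            raise BioTagError(
                f"{len(self.tokens)} tokens vs {len(self.bio_tags)} tags"
            )
        prev_end = -1
        for surf, s, e in self.tokens:
            if not (prev_end <= s < e):
                raise CorpusError(f"token offsets not increasing at ({s},{e})")
            prev_end = e
        validate_bio(self.bio_tags)


def validate_bio(tags: Sequence[str]) -> None:
    """Raise BioTagError at the first invalid tag or transition."""
    prev = "O"
    for i, tag in enumerate(tags):
        if tag == "O":
            prev = tag
            continue
        if len(tag) < 3 or tag[1] != "-" or tag[0] not in "BI":
            raise BioTagError(f"malformed tag {tag!r} at position {i}", i)
        if tag[0] == "I":
            if prev == "O" or prev[2:] != tag[2:]:
                raise BioTagError(
                    f"I-tag {tag!r} at position {i} follows {prev!r}", i
                )
        prev = tag


def entities_to_bio(doc: Document, tokens: list[Token] | None = None) -> TokenizedDocument:
    """Convert a document's entities to token-aligned BIO tags.

    Tokens partially overlapping an entity are absorbed into it (the span is
    expanded outward to covering token boundaries, never truncated); a
    warning is logged when expansion occurs.
    """
    toks = tokens if tokens is not None else tokenize(doc.text)
    tags = ["O"] * len(toks)
    for ent in doc.entities:
        idx = [
            i for i, (_, s, e) in enumerate(toks) if s < ent.end and e > ent.start
        ]
        if not idx:
            logger.warning(
                "%s: entity [%d,%d) covers no token; skipped",
                doc.doc_id, ent.start, ent.end,
            )
            continue
        first, last = idx[0], idx[-1]
        if toks[first][1] < ent.start or toks[last][2] > ent.end:
            logger.warning(
                "%s: entity [%d,%d) not token-aligned; expanded to [%d,%d)",
                doc.doc_id, ent.start, ent.end, toks[first][1], toks[last][2],
            )
        tags[first] = f"B-{ent.label}"
        for i in idx[1:]:
            tags[i] = f"I-{ent.label}"
    return TokenizedDocument(toks, tags)


def bio_to_entities(tdoc: TokenizedDocument, text: str) -> list[Entity]:
    """Inverse of :func:`entities_to_bio` for token-aligned entities."""
    validate_bio(tdoc.bio_tags)
    entities: list[Entity] = []
    run_start: int | None = None
    run_end = 0
    run_label = ""

    def flush() -> None:
        nonlocal run_start
        if run_start is not None:
            entities.append(
                Entity(run_start, run_end, run_label, text[run_start:run_end])
            )
            run_start = None

    for (surf, s, e), tag in zip(tdoc.tokens, tdoc.bio_tags):
        if tag == "O":
            flush()
        elif tag.startswith("B-"):
            flush()
            run_start, run_end, run_label = s, e, tag[2:]
        else:  # I-
            run_end = e
    flush()
    return entities


def snap_to_tokens(
    start: int, end: int, tokens: Sequence[Token]
) -> tuple[int, int] | None:
    """Expand [start, end) outward to covering token boundaries.

    Returns None when the span overlaps no token (e.g. pure whitespace).
    """
    idx = [i for i, (_, s, e) in enumerate(tokens) if s < end and e > start]
    if not idx:
        return None
    return tokens[idx[0]][1], tokens[idx[-1]][2]


# ---------------------------------------------------------------------------
# CoNLL-style BIO files


def write_bio(corpus: Corpus, path: str | Path) -> None:
    """Write a two-column (token TAB tag) file, `#doc <id>` per document,
    blank line between sentences."""
    lines: list[str] = []
    for doc in corpus:
        lines.append(f"#doc {doc.doc_id}")
        tdoc = entities_to_bio(doc)
        by_offset = {s: (surf, tag) for (surf, s, _), tag in zip(tdoc.tokens, tdoc.bio_tags)}
        for ss, se in segment_sentences(doc.text) or ([(0, 0)] if not doc.text else []):
            for surf, s, e in tokenize(doc.text[ss:se]):
                surf_g, tag = by_offset[ss + s]
                lines.append(f"{surf_g}\t{tag}")
            lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_bio(path: str | Path) -> Corpus:
    """Read a CoNLL BIO file written by :func:`write_bio`.

    Character offsets are reconstructed by joining tokens with single spaces
    and sentences with newlines (no source text is stored in the format).
    """
    raw = Path(path).read_text(encoding="utf-8")
    docs: list[Document] = []
    labels: list[str] = []

    cur_id: str | None = None
    sentences: list[list[tuple[str, str]]] = []
    cur_sent: list[tuple[str, str]] = []

    def flush_doc(line_no: int) -> None:
        nonlocal sentences, cur_sent
        if cur_sent:
            sentences.append(cur_sent)
            cur_sent = []
        if cur_id is None:
            if sentences:
                _build_doc("doc_000", sentences, docs, labels)
            sentences = []
            return
        _build_doc(cur_id, sentences, docs, labels)
        sentences = []

    for line_no, line in enumerate(raw.split("\n"), start=1):
        if line.startswith("#doc "):
            flush_doc(line_no)
            cur_id = line[len("#doc ") :].strip()
            continue
        if not line.strip():
            if cur_sent:
                sentences.append(cur_sent)
                cur_sent = []
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise CorpusError(
                f"{path}: line {line_no}: expected 2 tab-separated columns, "
                f"got {len(cols)}"
            )
        tok, tag = cols
        prev = cur_sent[-1][1] if cur_sent else "O"
        if tag != "O" and (len(tag) < 3 or tag[1] != "-" or tag[0] not in "BI"):
            raise BioTagError(f"{path}: line {line_no}: malformed tag {tag!r}", line_no)
        if tag.startswith("I-") and (prev == "O" or prev[2:] != tag[2:]):
            raise BioTagError(
                f"{path}: line {line_no}: I-tag {tag!r} follows {prev!r}", line_no
            )
        cur_sent.append((tok, tag))
    flush_doc(-1)
    return Corpus(docs, labels)


def _build_doc(
    doc_id: str,
    sentences: list[list[tuple[str, str]]],
    docs: list[Document],
    labels: list[str],
) -> None:
    parts: list[str] = []
    tokens: list[Token] = []
    tags: list[str] = []
    pos = 0
    for i, sent in enumerate(sentences):
        if i > 0:
            parts.append("\n")
            pos += 1
        for j, (tok, tag) in enumerate(sent):
            if j > 0:
                parts.append(" ")
                pos += 1
            tokens.append((tok, pos, pos + len(tok)))
            tags.append(tag)
            parts.append(tok)
            pos += len(tok)
    text = "".join(parts)
    ents = bio_to_entities(TokenizedDocument(tokens, tags), text)
    for e in ents:
        if e.label not in labels:
            labels.append(e.label)
    docs.append(Document(doc_id, text, ents))


# ---------------------------------------------------------------------------
# BRAT-like standoff


def write_standoff(doc: Document, directory: str | Path) -> tuple[Path, Path]:
    """Write <doc_id>.txt and <doc_id>.ann (T-lines) into *directory*."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    txt = d / f"{doc.doc_id}.txt"
    ann = d / f"{doc.doc_id}.ann"
    txt.write_text(doc.text, encoding="utf-8")
    lines = [
        f"T{i + 1}\t{e.label} {e.start} {e.end}\t{e.text}"
        for i, e in enumerate(doc.entities)
    ]
    ann.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return txt, ann


def read_standoff(text_path: str | Path, ann_path: str | Path) -> Document:
    """Read a text file plus a BRAT-like `.ann` file of T-lines."""
    text = Path(text_path).read_text(encoding="utf-8")
    entities = []
    for line in Path(ann_path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or not line.startswith("T"):
            continue
        try:
            tid, mid, surf = line.split("\t")
            label, s_str, e_str = mid.rsplit(" ", 2)
            s, e = int(s_str), int(e_str)
        except ValueError as exc:
            raise CorpusError(f"{ann_path}: malformed annotation line {line!r}") from exc
        if not (0 <= s < e <= len(text)):
            raise CorpusError(
                f"{ann_path}: {tid}: offsets [{s},{e}) out of range for "
                f"text of length {len(text)}"
            )
        if text[s:e] != surf:
            raise CorpusError(
                f"{ann_path}: {tid}: annotation text {surf!r} does not match "
                f"document substring {text[s:e]!r}"
            )
        entities.append(Entity(s, e, label, surf))
    doc_id = Path(text_path).stem
    return Document(doc_id, text, entities)


# ---------------------------------------------------------------------------
# JSON-lines interchange


def write_jsonl(docs: Iterable[Document], path: str | Path, split: dict[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {
                "doc_id": d.doc_id,
                "text": d.text,
                "entities": [
                    {"start": e.start, "end": e.end, "label": e.label, "text": e.text}
                    for e in d.entities
                ],
            }
            if split and d.doc_id in split:
                rec["split"] = split[d.doc_id]
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path, labels: list[str] | None = None) -> Corpus:
    docs: list[Document] = []
    seen_labels: list[str] = []
    split: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            ents = [
                Entity(e["start"], e["end"], e["label"], e.get("text", ""))
                for e in rec.get("entities", [])
            ]
            for e in ents:
                if e.label not in seen_labels:
                    seen_labels.append(e.label)
            docs.append(Document(rec["doc_id"], rec["text"], ents))
            if "split" in rec:
                split[rec["doc_id"]] = rec["split"]
    return Corpus(docs, labels if labels is not None else seen_labels, split)
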
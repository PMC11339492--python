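"""HTML span-markup protocol: render gold entities inline and parse
(possibly mutated) marked-up annotator output back to source offsets.

Annotations travel inline as ``<span class="TYPE">...</span>`` regions in an
otherwise verbatim copy of the document text. Generative annotators do not
always reproduce the source verbatim, so parsing aligns the tag-stripped
output back to the source by minimum edit distance before recovering spans;
spans whose text cannot be anchored above a similarity threshold are dropped
rather than mis-placed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .corpus import Document, Entity, snap_to_tokens, tokenize

# Straight or curly quotes around the class value, case-insensitive tag name.
# Only span tags are part of the protocol; everything else is literal text.
_OPEN_RE = re.compile(
    r"<\s*span\s+class\s*=\s*[\"'“”‘’]"
    r"([^\"'“”‘’<>]*)"
    r"[\"'“”‘’]\s*>",
    re.IGNORECASE,
)
_CLOSE_RE = re.compile(r"<\s*/\s*span\s*>", re.IGNORECASE)

DIAGNOSTIC_KEYS = (
    "malformed_tag",
    "unknown_class",
    "unaligned_span_dropped",
    "nested_span_flattened",
    "overlap_dropped",
    "text_divergence_chars",
)


class MarkupError(ValueError):
    pass


class UnknownClassError(MarkupError):
    def __init__(self, cls: str):
        super().__init__(f"unknown span class {cls!r}")
        self.cls = cls


@dataclass(frozen=True)
class MarkupConfig:
    """Label <-> class-attribute mapping and parsing policy."""

    label_to_class: dict[str, str]
    unknown_class_policy: str = "drop"  # drop | error
    similarity_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.unknown_class_policy not in ("drop", "error"):
            raise MarkupError(
                f"unknown_class_policy must be 'drop' or 'error', "
                f"got {self.unknown_class_policy!r}"
            )
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise MarkupError("similarity_threshold must lie in [0, 1]")
        classes = list(self.label_to_class.values())
        if any(not c for c in classes) or len(set(classes)) != len(classes):
            raise MarkupError("span classes must be non-empty and unique per label")

    @property
    def class_to_label(self) -> dict[str, str]:
        return {c: l for l, c in self.label_to_class.items()}

    @property
    def labels(self) -> list[str]:
        return list(self.label_to_class)


def identity_config(labels: list[str], **kw) -> MarkupConfig:
    """A config whose class attribute equals the label itself."""
    return MarkupConfig({l: l for l in labels}, **kw)


@dataclass
class ParseResult:
    """Entities in source coordinates plus parse diagnostics."""

    entities: list[Entity]
    diagnostics: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in DIAGNOSTIC_KEYS}
    )


def render_markup(doc: Document, cfg: MarkupConfig) -> str:
    """Wrap each entity of *doc* in a span tag, left to right.

    Stripping the tags from the result recovers ``doc.text`` exactly.
    """
    parts: list[str] = []
    pos = 0
    for e in doc.entities:
        if e.label not in cfg.label_to_class:
            raise MarkupError(f"label {e.label!r} has no class mapping")
        parts.append(doc.text[pos : e.start])
        parts.append(
            f'<span class="{cfg.label_to_class[e.label]}">'
            f"{doc.text[e.start:e.end]}</span>"
        )
        pos = e.end
    parts.append(doc.text[pos:])
    return "".join(parts)


def strip_tags(marked: str) -> tuple[str, list[tuple[int, int, str]], dict[str, int]]:
    """Remove span tags; return (plain text, spans in plain coordinates,
    diagnostics).

    Nested spans are flattened to the outermost (flagged); an open tag with
    no matching close is closed at the next newline or end of input
    (flagged); a stray close tag is removed and flagged.
    """
    plain: list[str] = []
    plen = 0
    spans: list[tuple[int, int, str]] = []
    diag = {k: 0 for k in DIAGNOSTIC_KEYS}
    stack: list[tuple[int, str]] = []  # (plain start, class)
    pos = 0

    def emit_literal(chunk: str) -> None:
        nonlocal plen
        while stack and "\n" in chunk:
            nl = chunk.index("\n")
            plain.append(chunk[: nl + 1])
            plen += nl + 1
            # unclosed span: close at end of line
            start, cls = stack.pop(0)
            for _ in range(len(stack)):
                stack.pop()
            spans.append((start, plen - 1, cls))
            diag["malformed_tag"] += 1
            chunk = chunk[nl + 1 :]
        plain.append(chunk)
        plen += len(chunk)

    while pos < len(marked):
        mo = _OPEN_RE.search(marked, pos)
        mc = _CLOSE_RE.search(marked, pos)
        nxt = min((m for m in (mo, mc) if m), key=lambda m: m.start(), default=None)
        if nxt is None:
            emit_literal(marked[pos:])
            break
        emit_literal(marked[pos : nxt.start()])
        if nxt is mo:
            if stack:
                diag["nested_span_flattened"] += 1
            stack.append((plen, mo.group(1)))
        else:
            if not stack:
                diag["malformed_tag"] += 1
            else:
                start, cls = stack[0]
                stack.pop()
                if not stack:
                    spans.append((start, plen, cls))
        pos = nxt.end()
    while stack:
        start, cls = stack.pop(0)
        for _ in range(len(stack)):
            stack.pop()
        spans.append((start, plen, cls))
        diag["malformed_tag"] += 1
    return "".join(plain), spans, diag


@dataclass
class OffsetMap:
    """Monotone map from output (plain) positions to source positions."""

    src_index: list[int]  # per plain char: aligned source index, or -1
    aligned: list[bool]  # True where the char aligns to a source char
    distance: int  # total edit distance plain <-> source

    def map_span(self, start: int, end: int) -> tuple[int, int] | None:
        """Map a plain-coordinate span to source coordinates.

        Returns None when no character of the span aligns to the source
        (a fully inserted, i.e. hallucinated, region).
        """
        idx = [
            self.src_index[i]
            for i in range(start, min(end, len(self.src_index)))
            if self.aligned[i]
        ]
        if not idx:
            return None
        return idx[0], idx[-1] + 1


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def align_texts(source: str, plain_output: str) -> OffsetMap:
    """Minimum-edit-distance character alignment of output to source.

    Unit costs, matches free. Output positions inserted by the annotator
    (absent from the source) map to the nearest preceding source position
    and are marked unaligned. Identical strings yield the identity map.
    """
    if not plain_output:
        return OffsetMap([], [], len(source))
    if not source:
        return OffsetMap([-1] * len(plain_output), [False] * len(plain_output),
                         len(plain_output))
    res = edlib.align(plain_output, source, task="path", mode="NW")
    src_index: list[int] = []
    aligned: list[bool] = []
    q = t = 0  # query (plain_output) / target (source) cursors
    for m in _CIGAR_RE.finditer(res["cigar"]):
        n, op = int(m.group(1)), m.group(2)
        if op in ("=", "X", "M"):
            for _ in range(n):
                src_index.append(t)
                aligned.append(True)
                q += 1
                t += 1
        elif op == "I":  # present in output, absent from source
            for _ in range(n):
                src_index.append(t - 1)
                aligned.append(False)
                q += 1
        else:  # D: source char skipped by the output
            t += n
    return OffsetMap(src_index, aligned, res["editDistance"])


def similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity in [0, 1]."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def parse_markup(source: str, marked_output: str, cfg: MarkupConfig) -> ParseResult:
    """Parse marked-up annotator output into source-anchored entities.

    Pipeline: strip tags -> align plain output to source -> map each span,
    snap outward to token boundaries -> drop spans whose text diverges from
    the mapped source text beyond ``cfg.similarity_threshold`` -> resolve
    duplicates/overlaps keeping the leftmost-longest span.
    """
    plain, spans, diag = strip_tags(marked_output)
    omap = align_texts(source, plain)
    diag["text_divergence_chars"] = omap.distance
    tokens = tokenize(source)
    class_to_label = cfg.class_to_label

    candidates: list[Entity] = []
    for ps, pe, cls in spans:
        if cls not in class_to_label:
            if cfg.unknown_class_policy == "error":
                raise UnknownClassError(cls)
            diag["unknown_class"] += 1
            continue
        mapped = omap.map_span(ps, pe)
        if mapped is None:
            diag["unaligned_span_dropped"] += 1
            continue
        snapped = snap_to_tokens(*mapped, tokens)
        if snapped is None:
            diag["unaligned_span_dropped"] += 1
            continue
        ss, se = snapped
        if similarity(plain[ps:pe].strip(), source[ss:se]) < cfg.similarity_threshold:
            diag["unaligned_span_dropped"] += 1
            continue
        candidates.append(Entity(ss, se, class_to_label[cls], source[ss:se]))

    # leftmost-longest de-overlap (flat NER), duplicates removed
    candidates.sort(key=lambda e: (e.start, -(e.end - e.start), e.label))
    kept: list[Entity] = []
    for e in candidates:
        if kept and e.start < kept[-1].end:
            diag["overlap_dropped"] += 1
            continue
        kept.append(e)
    return ParseResult(kept, diag)
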
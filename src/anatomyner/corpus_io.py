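"""Annotated-document model and corpus I/O.

Documents are tokenized sentences carrying two independent annotation
layers — anatomy spans (``explicit`` / ``implicit``) and medical-concept
spans (``disease`` / ``test`` / ``treatment``) — plus coreference chains
that tie local abbreviations to their full forms.  Span offsets are
token-level, 0-based and half-open.

Two on-disk formats are supported: a CoNLL-style BIO TSV (one token per
line, blank line between sentences, ``-DOCSTART-`` line between
documents) and a JSON-lines document format that round-trips bit-exactly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

ANATOMY_LABELS = ("explicit", "implicit")
CONCEPT_LABELS = ("disease", "test", "treatment")

_PUNCT = ".,;:!?()[]{}\"'`"


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class EntitySpan:
    """A labeled token range within one sentence, half-open [start, end)."""

    sentence_index: int
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span boundaries [{self.start}, {self.end})")

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.sentence_index, self.start, self.end)

    def covers(self, sentence_index: int, token_index: int) -> bool:
        return (
            sentence_index == self.sentence_index
            and self.start <= token_index < self.end
        )


@dataclass(frozen=True)
class Mention:
    """An unlabeled token range used inside coreference chains."""

    sentence_index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid mention boundaries [{self.start}, {self.end})")


@dataclass(frozen=True)
class CorefChain:
    chain_id: str
    mentions: tuple[Mention, ...]

    def __post_init__(self) -> None:
        if len(self.mentions) < 2:
            raise ValueError(f"chain {self.chain_id!r} needs >= 2 mentions")


@dataclass
class Document:
    doc_id: str
    sentences: list[list[str]]
    anatomy_spans: list[EntitySpan] = field(default_factory=list)
    concept_spans: list[EntitySpan] = field(default_factory=list)
    chains: list[CorefChain] = field(default_factory=list)

    def spans_for(self, layer: str) -> list[EntitySpan]:
        if layer == "anatomy":
            return self.anatomy_spans
        if layer == "concepts":
            return self.concept_spans
        raise ValueError(f"unknown layer {layer!r}")

    def validate(self) -> None:
        n = len(self.sentences)
        for name, spans, labels in (
            ("anatomy", self.anatomy_spans, ANATOMY_LABELS),
            ("concepts", self.concept_spans, CONCEPT_LABELS),
        ):
            for sp in spans:
                if sp.label not in labels:
                    raise ValueError(
                        f"{self.doc_id}: label {sp.label!r} not valid in layer {name}"
                    )
                if not (0 <= sp.sentence_index < n):
                    raise ValueError(f"{self.doc_id}: sentence index out of range: {sp}")
                if sp.end > len(self.sentences[sp.sentence_index]):
                    raise ValueError(f"{self.doc_id}: span exceeds sentence: {sp}")
            _check_no_overlap(spans, self.doc_id, name)
        for chain in self.chains:
            for m in chain.mentions:
                if not (0 <= m.sentence_index < n) or m.end > len(
                    self.sentences[m.sentence_index]
                ):
                    raise ValueError(
                        f"{self.doc_id}: chain {chain.chain_id} mention out of range"
                    )


def _check_no_overlap(spans: list[EntitySpan], doc_id: str, layer: str) -> None:
    by_sentence: dict[int, list[EntitySpan]] = {}
    for sp in spans:
        by_sentence.setdefault(sp.sentence_index, []).append(sp)
    for sent_spans in by_sentence.values():
        ordered = sorted(sent_spans, key=lambda s: (s.start, s.end))
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"{doc_id}: overlapping {layer} spans {a} / {b}")


# ---------------------------------------------------------------------------
# Tokenization


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with leading/trailing punctuation split off."""
    tokens: list[str] = []
    for chunk in text.split():
        head: list[str] = []
        tail: list[str] = []
        while len(chunk) > 1 and chunk[0] in _PUNCT:
            head.append(chunk[0])
            chunk = chunk[1:]
        while len(chunk) > 1 and chunk[-1] in _PUNCT:
            tail.append(chunk[-1])
            chunk = chunk[:-1]
        tokens.extend(head)
        if chunk:
            tokens.append(chunk)
        tokens.extend(reversed(tail))
    return tokens


_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    """Split on ./!/? followed by whitespace and a capital or digit.

    Over-splitting at abbreviation periods is tolerated by downstream
    consumers (the knowledge-feature flags are robust to it).
    """
    parts = [p.strip() for p in _SENT_BOUNDARY.split(text)]
    return [p for p in parts if p]


# ---------------------------------------------------------------------------
# BIO conversion


def spans_to_bio(
    spans: list[EntitySpan],
    sentence_length: int,
    tagged: bool = False,
) -> list[str]:
    """Encode non-overlapping spans of one sentence as a BIO tag sequence.

    With ``tagged=True`` tags carry the class suffix (``B-disease`` …)
    for multi-class layers; otherwise plain ``B``/``I``/``O``.
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping spans {a} / {b}")
    tags = ["O"] * sentence_length
    for sp in ordered:
        if sp.end > sentence_length:
            raise ValueError(f"span {sp} exceeds sentence length {sentence_length}")
        suffix = f"-{sp.label}" if tagged else ""
        tags[sp.start] = "B" + suffix
        for i in range(sp.start + 1, sp.end):
            tags[i] = "I" + suffix
    return tags


def bio_to_spans(
    tags: list[str],
    sentence_index: int = 0,
    default_label: str = "explicit",
) -> list[EntitySpan]:
    """Decode a BIO tag sequence into spans, leniently.

    Maximal ``B I…`` runs become spans.  A dangling ``I`` (after ``O``, at
    sentence start, or with a class suffix differing from the open span)
    opens a new span; this repair is logged rather than rejected.
    """
    spans: list[EntitySpan] = []
    start: int | None = None
    label = default_label
    for i, tag in enumerate(tags):
        kind, _, suffix = tag.partition("-")
        tag_label = suffix or default_label
        if kind == "B":
            if start is not None:
                spans.append(EntitySpan(sentence_index, start, i, label))
            start, label = i, tag_label
        elif kind == "I":
            if start is None or tag_label != label:
                if start is not None:
                    spans.append(EntitySpan(sentence_index, start, i, label))
                else:
                    logger.debug(
                        "dangling I at sentence %d token %d repaired to B",
                        sentence_index,
                        i,
                    )
                start, label = i, tag_label
        elif kind == "O":
            if start is not None:
                spans.append(EntitySpan(sentence_index, start, i, label))
                start = None
        else:
            raise FormatError(f"unknown BIO tag {tag!r}")
    if start is not None:
        spans.append(EntitySpan(sentence_index, start, len(tags), label))
    return spans


def document_tags(doc: Document, layer: str, label: str | None = None) -> list[list[str]]:
    """Per-sentence BIO tags for one layer of a document.

    ``layer='anatomy'`` with ``label='explicit'|'implicit'`` gives the
    binary tagging for one anatomy class; ``layer='concepts'`` gives the
    multi-class ``B-x``/``I-x`` tagging.
    """
    spans = doc.spans_for(layer)
    if label is not None:
        spans = [sp for sp in spans if sp.label == label]
    tagged = layer == "concepts"
    out = []
    for i, sentence in enumerate(doc.sentences):
        sent_spans = [sp for sp in spans if sp.sentence_index == i]
        out.append(spans_to_bio(sent_spans, len(sentence), tagged=tagged))
    return out


# ---------------------------------------------------------------------------
# CoNLL-style BIO TSV

_DOCSTART = "-DOCSTART-"


def write_bio(docs: list[Document], path, layer: str = "anatomy") -> None:
    """Write documents as CoNLL-style TSV: TOKEN, TAG_ANATOMY, TAG_CONCEPT."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(f"{_DOCSTART}\t{doc.doc_id}\n")
            anat = [
                document_tags(doc, "anatomy", label=lab)
                for lab in ANATOMY_LABELS
            ]
            conc = document_tags(doc, "concepts")
            merged_anat = _merge_layer_tags(anat, ANATOMY_LABELS)
            for s, sentence in enumerate(doc.sentences):
                for t, token in enumerate(sentence):
                    fh.write(f"{token}\t{merged_anat[s][t]}\t{conc[s][t]}\n")
                fh.write("\n")


def _merge_layer_tags(
    per_label: list[list[list[str]]], labels: tuple[str, ...]
) -> list[list[str]]:
    n_sent = len(per_label[0])
    merged = []
    for s in range(n_sent):
        row = ["O"] * len(per_label[0][s])
        for tags, lab in zip(per_label, labels):
            for t, tag in enumerate(tags[s]):
                if tag != "O":
                    row[t] = f"{tag}-{lab}"
        merged.append(row)
    return merged


def read_bio(path, layer: str = "anatomy") -> list[Document]:
    """Read a CoNLL-style BIO TSV written by :func:`write_bio`.

    Malformed I-after-O sequences are repaired to B (logged).  Unknown tag
    symbols raise :class:`FormatError` naming the line number.
    """
    docs: list[Document] = []
    cur_id: str | None = None
    sentences: list[list[str]] = []
    anat_tags: list[list[str]] = []
    conc_tags: list[list[str]] = []
    tokens: list[str] = []
    arow: list[str] = []
    crow: list[str] = []

    def flush_sentence() -> None:
        if tokens:
            sentences.append(list(tokens))
            anat_tags.append(list(arow))
            conc_tags.append(list(crow))
            tokens.clear()
            arow.clear()
            crow.clear()

    def flush_doc() -> None:
        nonlocal cur_id
        flush_sentence()
        if cur_id is None and not sentences:
            return
        doc = Document(doc_id=cur_id or f"doc{len(docs)}", sentences=list(sentences))
        doc.anatomy_spans = _decode_layer(anat_tags, ANATOMY_LABELS)
        doc.concept_spans = _decode_layer(conc_tags, CONCEPT_LABELS)
        doc.validate()
        docs.append(doc)
        sentences.clear()
        anat_tags.clear()
        conc_tags.clear()
        cur_id = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush_sentence()
                continue
            cols = line.split("\t")
            if cols[0] == _DOCSTART:
                flush_doc()
                cur_id = cols[1] if len(cols) > 1 else None
                continue
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            for col in cols[1:3]:
                if col.partition("-")[0] not in ("B", "I", "O"):
                    raise FormatError(f"{path}:{lineno}: unknown tag symbol {col!r}")
            tokens.append(cols[0])
            arow.append(cols[1])
            crow.append(cols[2] if len(cols) > 2 else "O")
    flush_doc()
    return docs


def _decode_layer(
    tag_rows: list[list[str]], labels: tuple[str, ...]
) -> list[EntitySpan]:
    spans: list[EntitySpan] = []
    for s, row in enumerate(tag_rows):
        per_label: dict[str, list[str]] = {lab: ["O"] * len(row) for lab in labels}
        for t, tag in enumerate(row):
            kind, _, suffix = tag.partition("-")
            if kind == "O":
                continue
            lab = suffix if suffix in labels else labels[0]
            per_label[lab][t] = kind
        for lab, tags in per_label.items():
            spans.extend(bio_to_spans(tags, sentence_index=s, default_label=lab))
    return spans


# ---------------------------------------------------------------------------
# JSON-lines document format


def document_to_record(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "sentences": doc.sentences,
        "anatomy_spans": [
            [sp.sentence_index, sp.start, sp.end, sp.label] for sp in doc.anatomy_spans
        ],
        "concept_spans": [
            [sp.sentence_index, sp.start, sp.end, sp.label] for sp in doc.concept_spans
        ],
        "chains": [
            {
                "chain_id": ch.chain_id,
                "mentions": [[m.sentence_index, m.start, m.end] for m in ch.mentions],
            }
            for ch in doc.chains
        ],
    }


def document_from_record(rec: dict) -> Document:
    doc = Document(
        doc_id=rec["doc_id"],
        sentences=[list(s) for s in rec["sentences"]],
        anatomy_spans=[EntitySpan(*sp) for sp in rec["anatomy_spans"]],
        concept_spans=[EntitySpan(*sp) for sp in rec["concept_spans"]],
        chains=[
            CorefChain(
                chain_id=ch["chain_id"],
                mentions=tuple(Mention(*m) for m in ch["mentions"]),
            )
            for ch in rec["chains"]
        ],
    )
    doc.validate()
    return doc


def write_jsonl(docs: list[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(document_to_record(doc), sort_keys=True) + "\n")


def read_jsonl(path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                docs.append(document_from_record(json.loads(line)))
    return docs


# ---------------------------------------------------------------------------
# Abbreviation substitution (optional mode)


def expand_abbreviations(doc: Document) -> Document:
    """Rewrite abbreviation mentions to the full form of their chain.

    An abbreviation mention is any single-token mention of a chain that is
    strictly shorter (in characters) than the chain's longest mention; the
    replacement is the token sequence of that longest mention.  Spans and
    chains are re-indexed to the rewritten sentences.  The default
    pipeline uses the coreference feature instead; this substitution mode
    is opt-in.
    """
    sentences = [list(s) for s in doc.sentences]
    edits: list[tuple[int, int, list[str]]] = []  # (sentence, position, replacement)
    for chain in doc.chains:
        full = max(
            chain.mentions,
            key=lambda m: len(" ".join(sentences[m.sentence_index][m.start : m.end])),
        )
        full_tokens = list(doc.sentences[full.sentence_index][full.start : full.end])
        for m in chain.mentions:
            if m is full or (m.end - m.start) != 1:
                continue
            text = doc.sentences[m.sentence_index][m.start]
            if len(text) < len(" ".join(full_tokens)):
                edits.append((m.sentence_index, m.start, full_tokens))

    # apply right-to-left per sentence so earlier offsets stay valid
    edits.sort(key=lambda e: (e[0], -e[1]))
    shift_maps: dict[int, list[tuple[int, int]]] = {}
    for s, pos, repl in edits:
        sentences[s][pos : pos + 1] = repl
        shift_maps.setdefault(s, []).append((pos, len(repl) - 1))

    def shift(s: int, offset: int, is_end: bool) -> int:
        delta = 0
        for pos, d in shift_maps.get(s, []):
            if offset > pos or (is_end and offset == pos + 1):
                delta += d if offset > pos else d
        return offset + delta

    def move_span(sp: EntitySpan) -> EntitySpan:
        return replace(
            sp,
            start=shift(sp.sentence_index, sp.start, False),
            end=shift(sp.sentence_index, sp.end, True),
        )

    new = Document(
        doc_id=doc.doc_id,
        sentences=sentences,
        anatomy_spans=[move_span(sp) for sp in doc.anatomy_spans],
        concept_spans=[move_span(sp) for sp in doc.concept_spans],
        chains=[
            CorefChain(
                chain_id=ch.chain_id,
                mentions=tuple(
                    Mention(
                        m.sentence_index,
                        shift(m.sentence_index, m.start, False),
                        shift(m.sentence_index, m.end, True),
                    )
                    for m in ch.mentions
                ),
            )
            for ch in doc.chains
        ],
    )
    new.validate()
    return new
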
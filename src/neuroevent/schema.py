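"""Event schema: categories, annotation encodings, corpus I/O and provenance mapping.

The type system covers six event categories, nine argument categories and
three attribute categories.  Two per-sentence encodings are supported: a BIO
tag per token for element spans, and per-token link rows tying arguments to
triggers and attributes to arguments.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

# --------------------------------------------------------------------------
# closed label sets
# --------------------------------------------------------------------------

#: event category -> BIO tag abbreviation
TRIGGER_ABBREV = {
    "Activate": "Act",
    "Deactivate": "Dea",
    "Effect": "Eff",
    "PerformExperiment": "Exp",
    "Acquisition": "Acq",
    "PerformAnalysis": "Ana",
}
ABBREV_TO_EVENT = {v: k for k, v in TRIGGER_ABBREV.items()}
EVENT_CATEGORIES = tuple(TRIGGER_ABBREV)

ARGUMENT_CODES = ("BRI", "COG", "ACQ", "SEN", "STP", "TSK", "AOB", "TOL", "RLT")
ATTRIBUTE_CODES = ("ACQ_A", "SEN_A", "STP_A")
#: attribute category -> the argument category it modifies
ATTRIBUTE_HOST = {"ACQ_A": "ACQ", "SEN_A": "SEN", "STP_A": "STP"}
ATTRIBUTE_BEARING = tuple(ATTRIBUTE_HOST.values())

#: all span labels usable in BIO tags, in a fixed order
SPAN_CATEGORIES = tuple(TRIGGER_ABBREV.values()) + ARGUMENT_CODES + ATTRIBUTE_CODES

#: the 37-label element tag set; index 0 is "O"
ELEMENT_TAGS = ("O",) + tuple(
    f"{p}-{cat}" for cat in SPAN_CATEGORIES for p in ("B", "I")
)
ELEMENT_TAG_INDEX = {t: i for i, t in enumerate(ELEMENT_TAGS)}


@dataclass(frozen=True)
class RoleSlot:
    """One role slot of an event category.

    ``arity`` is "one" (exactly one), "*" (zero or more) or "+" (one or more).
    """

    role: str
    categories: frozenset[str]
    arity: str


def _slots(*triples) -> tuple[RoleSlot, ...]:
    return tuple(RoleSlot(r, frozenset(c), a) for r, c, a in triples)


# Role inventories per event category.  The "from" slot of Acquisition also
# admits BRI: the worked annotation example links a brain-area span to an
# Acquisition trigger through this role.
EVENT_SLOTS: dict[str, tuple[RoleSlot, ...]] = {
    "Activate": _slots(("cause", ["COG"], "one"), ("affect", ["BRI"], "+")),
    "Deactivate": _slots(("cause", ["COG"], "one"), ("affect", ["BRI"], "+")),
    "Effect": _slots(("cause", ["COG"], "one"), ("affect", ["BRI"], "+")),
    "PerformExperiment": _slots(
        ("participates_in", ["STP"], "*"),
        ("uses", ["TSK"], "+"),
        ("by", ["SEN"], "*"),
    ),
    "Acquisition": _slots(
        ("produces", ["AOB"], "*"),
        ("uses", ["ACQ"], "+"),
        ("from", ["STP", "BRI"], "*"),
    ),
    "PerformAnalysis": _slots(
        ("produces", ["RLT"], "+"),
        ("on", ["AOB"], "*"),
        ("uses", ["TOL"], "+"),
    ),
}

#: the 18-label relation set used by the relation layer: 14 event-qualified
#: roles, 3 attribute relations, and "none" for unattached tokens.
#: ``Acquisition-from`` is deliberately absent (it never occurs as a scored
#: relation), although the schema keeps the role slot for link encoding.
RELATION_LABELS = (
    "Activate-cause",
    "Activate-affect",
    "Deactivate-cause",
    "Deactivate-affect",
    "Effect-cause",
    "Effect-affect",
    "PerformExperiment-participates_in",
    "PerformExperiment-uses",
    "PerformExperiment-by",
    "Acquisition-produces",
    "Acquisition-uses",
    "PerformAnalysis-produces",
    "PerformAnalysis-on",
    "PerformAnalysis-uses",
    "ACQ-attribute",
    "SEN-attribute",
    "STP-attribute",
    "none",
)
RELATION_INDEX = {r: i for i, r in enumerate(RELATION_LABELS)}
NONE_RELATION = "none"

#: role name as written in annotation files ("participates_in" -> "Participates in")
ROLE_DISPLAY = {
    "cause": "Cause",
    "affect": "Affect",
    "participates_in": "Participates in",
    "uses": "Uses",
    "by": "By",
    "produces": "Produces",
    "on": "On",
    "from": "From",
}
DISPLAY_TO_ROLE = {v: k for k, v in ROLE_DISPLAY.items()}
TRIGGER_ROW_LABEL = "Trigger"


class SchemaError(ValueError):
    """Raised on malformed annotations or labels outside the closed sets."""


# --------------------------------------------------------------------------
# core data types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    text: str
    position: int  # 1-based
    char_start: int = 0
    char_end: int = 0


@dataclass(frozen=True, order=True)
class Span:
    """A labelled token span; positions are 1-based and inclusive."""

    start: int
    end: int
    label: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise SchemaError(f"bad span boundaries {self.start}..{self.end}")
        if self.label not in SPAN_CATEGORIES:
            raise SchemaError(f"unknown span label {self.label!r}")

    def overlaps(self, other: "Span") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class EventMention:
    category: str
    trigger: Span
    role_links: list[tuple[str, Span]] = field(default_factory=list)
    attribute_links: list[tuple[Span, Span]] = field(default_factory=list)  # (arg, attr)

    def spans(self) -> list[Span]:
        out = [self.trigger] + [s for _, s in self.role_links]
        out += [a for _, a in self.attribute_links]
        return out


@dataclass
class AnnotatedSentence:
    tokens: list[Token]
    element_tags: list[str]
    #: per token: (role label or "Trigger" or "", positions list)
    link_rows: list[tuple[str, list[int]]]

    def __post_init__(self):
        n = len(self.tokens)
        if len(self.element_tags) != n or len(self.link_rows) != n:
            raise SchemaError("tokens, tags and link rows must have equal length")

    @property
    def words(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass
class ProvenanceDocument:
    records: list[dict]
    relations: list[dict]

    def to_prov_json(self) -> dict:
        doc: dict = {"activity": {}, "entity": {}, "agent": {}, "attribute": {}}
        for rec in self.records:
            doc[rec["kind"]][rec["id"]] = {"label": rec["label"], "type": rec["type"]}
        for kind in ("used", "generated", "associated_with", "has_attribute"):
            doc[kind] = {}
        for i, rel in enumerate(self.relations):
            doc[rel["kind"]][f"_:{rel['kind']}{i}"] = {
                "from": rel["from"],
                "to": rel["to"],
                "role": rel["role"],
            }
        return doc


# --------------------------------------------------------------------------
# BIO encoding
# --------------------------------------------------------------------------


def encode_bio(spans: Iterable[Span], n: int) -> list[str]:
    """Encode non-overlapping spans over an ``n``-token sentence as BIO tags."""
    spans = sorted(spans)
    for a, b in zip(spans, spans[1:]):
        if a.overlaps(b):
            raise SchemaError(f"overlapping spans {a} and {b}")
    tags = ["O"] * n
    for sp in spans:
        if sp.end > n:
            raise SchemaError(f"span {sp} outside sentence of length {n}")
        tags[sp.start - 1] = f"B-{sp.label}"
        for i in range(sp.start, sp.end):
            tags[i] = f"I-{sp.label}"
    return tags


def decode_bio(tags: Sequence[str]) -> list[Span]:
    """Decode BIO tags into spans.

    A stray ``I-X`` (no preceding ``B-X``/``I-X``) is repaired to ``B-X``
    rather than rejected, so model output always decodes.
    """
    spans: list[Span] = []
    cur_label, cur_start = None, 0
    for i, tag in enumerate(tags, start=1):
        if tag not in ELEMENT_TAG_INDEX:
            raise SchemaError(f"unknown tag {tag!r} at position {i}")
        if tag == "O":
            prefix, label = "O", None
        else:
            prefix, label = tag.split("-", 1)
        if prefix == "I" and label == cur_label:
            continue
        if cur_label is not None:
            spans.append(Span(cur_start, i - 1, cur_label))
        cur_label = label  # I with a different label acts as B (repair)
        cur_start = i
    if cur_label is not None:
        spans.append(Span(cur_start, len(tags), cur_label))
    return spans


# --------------------------------------------------------------------------
# link rows
# --------------------------------------------------------------------------


def encode_link_rows(mention: EventMention, n: int) -> list[tuple[str, list[int]]]:
    """Produce per-token (role label, position list) rows for one mention.

    The trigger row lists the start positions of its arguments; every token
    of an argument span carries the role label, and the span-start row lists
    the start positions of attached attributes.
    """
    for sp in mention.spans():
        if sp.end > n:
            raise SchemaError(f"span {sp} outside sentence of length {n}")
    rows: list[tuple[str, list[int]]] = [("", []) for _ in range(n)]
    arg_starts = sorted(sp.start for _, sp in mention.role_links)
    for i in range(mention.trigger.start, mention.trigger.end + 1):
        rows[i - 1] = (TRIGGER_ROW_LABEL, arg_starts if i == mention.trigger.start else [])
    attrs_by_arg: dict[int, list[int]] = {}
    for arg, attr in mention.attribute_links:
        attrs_by_arg.setdefault(arg.start, []).append(attr.start)
    for role, sp in mention.role_links:
        label = ROLE_DISPLAY.get(role, role)
        for i in range(sp.start, sp.end + 1):
            positions = sorted(attrs_by_arg.get(sp.start, [])) if i == sp.start else []
            rows[i - 1] = (label, positions)
    return rows


def decode_mentions(sentence: AnnotatedSentence) -> list[EventMention]:
    """Reconstruct event mentions from a sentence's tags and link rows."""
    spans = decode_bio(sentence.element_tags)
    by_start = {sp.start: sp for sp in spans}
    mentions = []
    for sp in spans:
        if sp.label not in ABBREV_TO_EVENT:
            continue
        category = ABBREV_TO_EVENT[sp.label]
        _, arg_positions = sentence.link_rows[sp.start - 1]
        role_links, attribute_links = [], []
        for pos in arg_positions:
            arg = by_start.get(pos)
            if arg is None:
                raise SchemaError(f"link position {pos} is not a span start")
            display, attr_positions = sentence.link_rows[pos - 1]
            role = DISPLAY_TO_ROLE.get(display, display)
            role_links.append((role, arg))
            for apos in attr_positions:
                attr = by_start.get(apos)
                if attr is None:
                    raise SchemaError(f"attribute position {apos} is not a span start")
                attribute_links.append((arg, attr))
        mentions.append(
            EventMention(category, sp, role_links, attribute_links)
        )
    return mentions


def sentence_from_mention(tokens: list[Token], mention: EventMention) -> AnnotatedSentence:
    """Assemble the two encodings of one mention into an annotated sentence."""
    n = len(tokens)
    tags = encode_bio(mention.spans(), n)
    rows = encode_link_rows(mention, n)
    return AnnotatedSentence(tokens, tags, rows)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------


def validate_event(mention: EventMention) -> list[str]:
    """Return schema violations (empty list means the mention is valid)."""
    violations = []
    if mention.category not in EVENT_SLOTS:
        return [f"unknown event category {mention.category!r}"]
    if mention.trigger.label != TRIGGER_ABBREV[mention.category]:
        violations.append(
            f"trigger label {mention.trigger.label!r} does not match "
            f"category {mention.category}"
        )
    slots = {s.role: s for s in EVENT_SLOTS[mention.category]}
    counts = {r: 0 for r in slots}
    for role, sp in mention.role_links:
        slot = slots.get(role)
        if slot is None:
            violations.append(f"role {role!r} not admissible for {mention.category}")
            continue
        counts[role] += 1
        if sp.label not in slot.categories:
            violations.append(
                f"argument category {sp.label} not admissible for role {role!r}"
            )
    for role, slot in slots.items():
        if slot.arity == "one" and counts[role] != 1:
            violations.append(f"role {role!r} requires exactly one argument")
        elif slot.arity == "+" and counts[role] < 1:
            violations.append(f"role {role!r} requires at least one argument")
    linked_args = {sp for _, sp in mention.role_links}
    for arg, attr in mention.attribute_links:
        if arg not in linked_args:
            violations.append(f"attribute host {arg} is not a linked argument")
        if arg.label not in ATTRIBUTE_BEARING:
            violations.append(
                f"attributes cannot attach to category {arg.label}"
            )
        elif ATTRIBUTE_HOST.get(attr.label) != arg.label:
            violations.append(
                f"attribute {attr.label} is not paired with {arg.label}"
            )
    return violations


# --------------------------------------------------------------------------
# corpus I/O (tab-separated, one token per line, blank line between sentences)
# --------------------------------------------------------------------------

_POSLIST_RE = re.compile(r"^\[(\d+(?:,\d+)*)?\]$")


def _format_row(token: Token, tag: str, row: tuple[str, list[int]]) -> str:
    label, positions = row
    pos_str = f"[{','.join(map(str, positions))}]" if positions else ""
    return f"{token.position}\t{token.text}\t{tag}\t{label}\t{pos_str}"


def write_corpus(path, sentences: Iterable[AnnotatedSentence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for tok, tag, row in zip(sent.tokens, sent.element_tags, sent.link_rows):
                fh.write(_format_row(tok, tag, row) + "\n")
            fh.write("\n")


def read_corpus(path) -> list[AnnotatedSentence]:
    sentences: list[AnnotatedSentence] = []
    tokens: list[Token] = []
    tags: list[str] = []
    rows: list[tuple[str, list[int]]] = []

    def flush():
        nonlocal tokens, tags, rows
        if tokens:
            sentences.append(AnnotatedSentence(tokens, tags, rows))
            tokens, tags, rows = [], [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise SchemaError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, "
                    f"got {len(parts)}"
                )
            pos_s, word, tag, label, poslist = parts
            try:
                position = int(pos_s)
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            if tag not in ELEMENT_TAG_INDEX:
                raise SchemaError(f"{path}:{lineno}: unknown tag {tag!r}")
            positions: list[int] = []
            if poslist:
                m = _POSLIST_RE.match(poslist)
                if not m:
                    raise SchemaError(
                        f"{path}:{lineno}: malformed position list {poslist!r}"
                    )
                if m.group(1):
                    positions = [int(x) for x in m.group(1).split(",")]
            start = sum(len(t.text) + 1 for t in tokens)
            tokens.append(Token(word, position, start, start + len(word)))
            tags.append(tag)
            rows.append((label, positions))
    flush()
    return sentences


# --------------------------------------------------------------------------
# provenance mapping
# --------------------------------------------------------------------------

#: argument category -> provenance record kind
_RECORD_KIND = {code: "entity" for code in ARGUMENT_CODES}
_RECORD_KIND["STP"] = "agent"
_RECORD_KIND["SEN"] = "agent"
_RECORD_KIND["TOL"] = "agent"

#: role -> provenance relation kind
_RELATION_KIND = {
    "uses": "used",
    "on": "used",
    "from": "used",
    "cause": "used",
    "produces": "generated",
    "affect": "generated",
    "participates_in": "associated_with",
    "by": "associated_with",
}


def events_to_provenance(
    mentions: Sequence[EventMention], sentence_words: Sequence[Sequence[str]] | None = None
) -> ProvenanceDocument:
    """Map validated mentions to a provenance document.

    Per mention: one activity, one entity/agent per argument, one attribute
    record per attribute, and one typed relation per link.
    """
    records, relations = [], []
    for mi, mention in enumerate(mentions):
        words = sentence_words[mi] if sentence_words is not None else None

        def text_of(sp: Span) -> str:
            if words is None:
                return f"{sp.label}@{sp.start}"
            return " ".join(words[sp.start - 1 : sp.end])

        act_id = f"activity:{mi}"
        records.append(
            {"kind": "activity", "id": act_id, "label": text_of(mention.trigger),
             "type": mention.category}
        )
        span_ids: dict[Span, str] = {}
        for ai, (role, sp) in enumerate(mention.role_links):
            rec_id = f"{_RECORD_KIND.get(sp.label, 'entity')}:{mi}.{ai}"
            span_ids[sp] = rec_id
            records.append(
                {"kind": _RECORD_KIND.get(sp.label, "entity"), "id": rec_id,
                 "label": text_of(sp), "type": sp.label}
            )
            relations.append(
                {"kind": _RELATION_KIND.get(role, "used"), "from": act_id,
                 "to": rec_id, "role": role}
            )
        for bi, (arg, attr) in enumerate(mention.attribute_links):
            rec_id = f"attribute:{mi}.{bi}"
            records.append(
                {"kind": "attribute", "id": rec_id, "label": text_of(attr),
                 "type": attr.label}
            )
            relations.append(
                {"kind": "has_attribute", "from": span_ids.get(arg, act_id),
                 "to": rec_id, "role": "attribute"}
            )
    return ProvenanceDocument(records, relations)


def write_prov_json(path, document: ProvenanceDocument) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(document.to_prov_json(), fh, indent=2, sort_keys=True)
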
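"""Dictionary-driven corpus bootstrapping.

Tokenization, gazetteer matching and the two sentence-level extraction
rules: a trigger plus two admissible arguments marks a complete mention
(Rule 1); a Deactivate trigger plus one brain-area argument suffices
(Rule 2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .schema import (
    ARGUMENT_CODES,
    ATTRIBUTE_CODES,
    ATTRIBUTE_HOST,
    EVENT_CATEGORIES,
    EVENT_SLOTS,
    TRIGGER_ABBREV,
    EventMention,
    SchemaError,
    Span,
    Token,
)

# words keep intra-word hyphens/apostrophes ("b-value" is one token);
# any other non-space character is a token of its own
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-'][A-Za-z0-9]+)*|[^\sA-Za-z0-9]")

DICTIONARY_CATEGORIES = tuple(EVENT_CATEGORIES) + ARGUMENT_CODES + ATTRIBUTE_CODES

# tie-break rank when several categories match the same span
def _category_rank(category: str) -> tuple[int, str]:
    if category in EVENT_CATEGORIES:
        kind = 0
    elif category in ARGUMENT_CODES:
        kind = 1
    else:
        kind = 2
    return (kind, category)


def tokenize(text: str) -> list[Token]:
    """Split text into position-indexed tokens with character offsets."""
    return [
        Token(m.group(), i, m.start(), m.end())
        for i, m in enumerate(_TOKEN_RE.finditer(text), start=1)
    ]


@dataclass
class DictionarySet:
    """Per-category gazetteers; each term is a tuple of lowercase tokens."""

    entries: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self):
        for category, terms in self.entries.items():
            if category not in DICTIONARY_CATEGORIES:
                raise SchemaError(f"unknown dictionary category {category!r}")
            for term in terms:
                if not term or any(not t for t in term):
                    raise SchemaError(f"empty term in category {category}")

    @classmethod
    def from_strings(cls, mapping: dict[str, Iterable[str]]) -> "DictionarySet":
        entries = {}
        for category, terms in mapping.items():
            entries[category] = [
                tuple(t.text.lower() for t in tokenize(term)) for term in terms
            ]
        return cls(entries)

    @classmethod
    def from_directory(cls, directory) -> "DictionarySet":
        """Load ``<CATEGORY>.txt`` files (one term per line) from a directory."""
        mapping: dict[str, list[str]] = {}
        for path in sorted(Path(directory).glob("*.txt")):
            category = path.stem
            if category not in DICTIONARY_CATEGORIES:
                raise SchemaError(f"unknown dictionary file {path.name}")
            terms = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
            mapping[category] = [t for t in terms if t]
        return cls.from_strings(mapping)

    def write_directory(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for category, terms in self.entries.items():
            lines = [" ".join(term) for term in terms]
            (directory / f"{category}.txt").write_text(
                "\n".join(lines) + "\n", encoding="utf-8"
            )


@dataclass(frozen=True)
class MatchedTerm:
    span: Span
    category: str  # dictionary category (event name, argument or attribute code)
    matched_text: str


def _span_label(category: str) -> str:
    return TRIGGER_ABBREV.get(category, category)


def match_terms(tokens: Sequence[Token], dicts: DictionarySet) -> list[MatchedTerm]:
    """Case-insensitive leftmost-longest non-overlapping gazetteer matching.

    Ties across categories on the same span are broken trigger > argument >
    attribute, then lexicographically by category code.
    """
    lower = [t.text.lower() for t in tokens]
    # term tuple -> categories containing it
    index: dict[tuple[str, ...], list[str]] = {}
    max_len = 0
    for category, terms in dicts.entries.items():
        for term in terms:
            index.setdefault(term, []).append(category)
            max_len = max(max_len, len(term))
    matches: list[MatchedTerm] = []
    i = 0
    n = len(tokens)
    while i < n:
        found = None
        for k in range(min(max_len, n - i), 0, -1):
            cats = index.get(tuple(lower[i : i + k]))
            if cats:
                category = min(cats, key=_category_rank)
                found = MatchedTerm(
                    Span(i + 1, i + k, _span_label(category)),
                    category,
                    " ".join(tok.text for tok in tokens[i : i + k]),
                )
                break
        if found is not None:
            matches.append(found)
            i = found.span.end
        else:
            i += 1
    return matches


@dataclass
class CandidateMention:
    """A trigger with the co-occurring matches the extraction rules accept."""

    trigger: MatchedTerm
    arguments: list[MatchedTerm]
    attributes: list[MatchedTerm]
    rule: int  # 1 or 2


def _admissible_codes(event: str) -> set[str]:
    codes: set[str] = set()
    for slot in EVENT_SLOTS[event]:
        codes |= slot.categories
    return codes


def extract_mentions(
    tokens: Sequence[Token], matches: Sequence[MatchedTerm]
) -> list[CandidateMention]:
    """Apply Rules 1 and 2 to gazetteer matches of one sentence."""
    triggers = [m for m in matches if m.category in EVENT_CATEGORIES]
    arguments = [m for m in matches if m.category in ARGUMENT_CODES]
    attributes = [m for m in matches if m.category in ATTRIBUTE_CODES]
    candidates = []
    for trig in triggers:
        admissible = _admissible_codes(trig.category)
        args = [a for a in arguments if a.category in admissible]
        if len(args) >= 2:
            candidates.append(CandidateMention(trig, args, list(attributes), rule=1))
        elif trig.category == "Deactivate" and any(
            a.category == "BRI" for a in args
        ):
            bri = [a for a in args if a.category == "BRI"]
            candidates.append(CandidateMention(trig, bri, list(attributes), rule=2))
    return candidates


def propose_links(candidate: CandidateMention) -> tuple[EventMention, list[MatchedTerm]]:
    """Link a candidate's matches into an event mention.

    Each argument takes its unique admissible role for the trigger's event
    category.  Attributes attach to the nearest argument of their paired
    category; when none is present they fall back to the nearest linked
    argument (the worked annotation example attaches an acquisition
    parameter to an acquisition-object argument).  Matches that cannot be
    linked are returned separately.
    """
    event = candidate.trigger.category
    unlinked: list[MatchedTerm] = []
    role_links: list[tuple[str, Span]] = []
    for arg in candidate.arguments:
        roles = [s.role for s in EVENT_SLOTS[event] if arg.category in s.categories]
        if not roles:
            unlinked.append(arg)
            continue
        role_links.append((roles[0], arg.span))
    attribute_links: list[tuple[Span, Span]] = []
    for attr in candidate.attributes:
        host_code = ATTRIBUTE_HOST[attr.category]
        hosts = [sp for _, sp in role_links if sp.label == host_code]
        if not hosts:
            hosts = [sp for _, sp in role_links]
        if not hosts:
            unlinked.append(attr)
            continue
        # nearest by start-position distance, ties to the left
        host = min(hosts, key=lambda sp: (abs(sp.start - attr.span.start), sp.start))
        attribute_links.append((host, attr.span))
    mention = EventMention(
        event, candidate.trigger.span, role_links, attribute_links
    )
    return mention, unlinked


def bootstrap_sentence(text: str, dicts: DictionarySet):
    """Full pipeline on one raw sentence: tokenize, match, extract, link.

    Returns (tokens, matches, [(mention, unlinked), ...]).
    """
    tokens = tokenize(text)
    matches = match_terms(tokens, dicts)
    results = [propose_links(c) for c in extract_mentions(tokens, matches)]
    return tokens, matches, results
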
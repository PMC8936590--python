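"""Synthetic annotated corpora with the structure the extractor assumes.

Each generated sentence carries exactly one event mention: a trigger term,
role slots filled according to the schema arities, optional attribute
tokens placed immediately before their argument, and distractor tokens
that match no gazetteer entry.  The default category mix follows the
observed corpus distribution (24/4/35/20/8/9%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bootstrap import DictionarySet
from .schema import (
    ARGUMENT_CODES,
    ATTRIBUTE_CODES,
    ATTRIBUTE_HOST,
    EVENT_CATEGORIES,
    EVENT_SLOTS,
    TRIGGER_ABBREV,
    AnnotatedSentence,
    EventMention,
    SchemaError,
    Span,
    Token,
    sentence_from_mention,
)

DEFAULT_PROPORTIONS = {
    "Activate": 0.24,
    "Deactivate": 0.04,
    "Effect": 0.35,
    "PerformExperiment": 0.20,
    "Acquisition": 0.08,
    "PerformAnalysis": 0.09,
}


@dataclass
class SynthConfig:
    seed: int = 0
    n_mentions: int = 100
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    trigger_vocab: int = 8
    argument_vocab: int = 12
    attribute_vocab: int = 6
    distractor_vocab: int = 30
    distractor_rate: float = 0.3
    attribute_rate: float = 0.5
    ambiguity_rate: float = 0.0
    multi_token_frac: float = 0.3
    optional_slot_rate: float = 0.5
    extra_argument_rate: float = 0.3

    def __post_init__(self):
        total = sum(self.category_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SchemaError("category proportions must sum to 1")
        for rate in (self.distractor_rate, self.attribute_rate,
                     self.ambiguity_rate, self.multi_token_frac,
                     self.optional_slot_rate, self.extra_argument_rate):
            if not 0.0 <= rate <= 1.0:
                raise SchemaError("rates must lie in [0, 1]")
        if set(self.category_proportions) != set(EVENT_CATEGORIES):
            raise SchemaError("proportions must cover exactly the six categories")


@dataclass
class SynthResources:
    dicts: DictionarySet
    distractors: list[str]


def _category_prefix(category: str) -> str:
    if category in TRIGGER_ABBREV:
        return "tr" + TRIGGER_ABBREV[category].lower()
    return category.replace("_", "").lower()


def build_resources(config: SynthConfig) -> SynthResources:
    """Create per-category term lists and a disjoint distractor vocabulary.

    Categories are pairwise disjoint unless ``ambiguity_rate`` > 0, in which
    case a fraction of argument terms is also inserted into the term list
    of the next argument category.
    """
    rng = np.random.default_rng(config.seed)
    entries: dict[str, list[tuple[str, ...]]] = {}
    sizes = (
        [(c, config.trigger_vocab) for c in EVENT_CATEGORIES]
        + [(c, config.argument_vocab) for c in ARGUMENT_CODES]
        + [(c, config.attribute_vocab) for c in ATTRIBUTE_CODES]
    )
    for category, size in sizes:
        prefix = _category_prefix(category)
        terms = []
        for i in range(max(size, 1)):
            # attribute terms stay single-token so they sit directly before
            # their argument at distance one
            if category not in ATTRIBUTE_CODES and rng.random() < config.multi_token_frac:
                terms.append((f"{prefix}w{i}", f"{prefix}x{i}"))
            else:
                terms.append((f"{prefix}w{i}",))
        entries[category] = terms
    if config.ambiguity_rate > 0:
        codes = list(ARGUMENT_CODES)
        for k, code in enumerate(codes):
            other = codes[(k + 1) % len(codes)]
            for term in entries[code]:
                if rng.random() < config.ambiguity_rate:
                    entries[other].append(term)
    distractors = [f"flrw{i}" for i in range(config.distractor_vocab)]
    return SynthResources(DictionarySet(entries), distractors)


def _sample_slot_fills(category: str, config: SynthConfig,
                       rng: np.random.Generator) -> list[tuple[str, str]]:
    """Choose (role, argument category) fills honoring the slot arities.

    The optional "from" slot of Acquisition is never filled: its qualified
    relation lies outside the scored relation set.
    """
    fills: list[tuple[str, str]] = []
    for slot in EVENT_SLOTS[category]:
        if category == "Acquisition" and slot.role == "from":
            continue
        code = sorted(slot.categories)[0]
        if slot.arity in ("one", "+"):
            fills.append((slot.role, code))
            if slot.arity == "+" and rng.random() < config.extra_argument_rate:
                fills.append((slot.role, code))
        elif rng.random() < config.optional_slot_rate:
            fills.append((slot.role, code))
    if len(fills) < 2:  # guarantee Rule-1 extractability
        optional = [
            (s.role, sorted(s.categories)[0])
            for s in EVENT_SLOTS[category]
            if s.arity == "*" and not (category == "Acquisition" and s.role == "from")
        ]
        if optional:
            fills.append(optional[int(rng.integers(len(optional)))])
        else:
            fills.append(fills[0])
    return fills


def _pick_term(terms, rng) -> tuple[str, ...]:
    return terms[int(rng.integers(len(terms)))]


def generate_sentence(
    category: str,
    resources: SynthResources,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[AnnotatedSentence, EventMention]:
    """One sentence containing one mention of the given event category."""
    entries = resources.dicts.entries
    host_to_attr = {v: k for k, v in ATTRIBUTE_HOST.items()}
    # chunks: (words, kind, role, category); attributes prepend their host chunk
    chunks: list[dict] = [
        {"words": list(_pick_term(entries[category], rng)), "kind": "trigger",
         "attr": None}
    ]
    for role, code in _sample_slot_fills(category, config, rng):
        chunk = {
            "words": list(_pick_term(entries[code], rng)),
            "kind": "argument", "role": role, "code": code, "attr": None,
        }
        attr_code = host_to_attr.get(code)
        if attr_code is not None and rng.random() < config.attribute_rate:
            chunk["attr"] = (
                _pick_term(entries[attr_code], rng)[0], attr_code
            )
        chunks.append(chunk)
    order = rng.permutation(len(chunks))
    words: list[str] = []
    placed: list[tuple[dict, int, int]] = []  # (chunk, start, end) 1-based

    def add_distractors(force: bool = False):
        count = 0
        if force:
            count = 1
        elif rng.random() < config.distractor_rate:
            count = int(rng.integers(1, 3))
        for _ in range(count):
            words.append(resources.distractors[int(rng.integers(len(resources.distractors)))])

    attr_spans: list[tuple[dict, Span]] = []
    for oi in order:
        chunk = chunks[oi]
        add_distractors()
        if chunk["attr"] is not None:
            # keep another argument from sitting at distance one to the left
            if words and not words[-1].startswith("flrw"):
                add_distractors(force=True)
            attr_word, attr_code = chunk["attr"]
            words.append(attr_word)
            attr_spans.append((chunk, Span(len(words), len(words), attr_code)))
        start = len(words) + 1
        words.extend(chunk["words"])
        placed.append((chunk, start, len(words)))
    add_distractors()

    trigger_span = None
    role_links: list[tuple[str, Span]] = []
    chunk_spans: dict[int, Span] = {}
    for chunk, start, end in placed:
        if chunk["kind"] == "trigger":
            trigger_span = Span(start, end, TRIGGER_ABBREV[category])
        else:
            sp = Span(start, end, chunk["code"])
            chunk_spans[id(chunk)] = sp
            role_links.append((chunk["role"], sp))
    attribute_links = [
        (chunk_spans[id(chunk)], attr_sp) for chunk, attr_sp in attr_spans
    ]
    mention = EventMention(category, trigger_span, role_links, attribute_links)
    offset = 0
    tokens = []
    for i, w in enumerate(words, start=1):
        tokens.append(Token(w, i, offset, offset + len(w)))
        offset += len(w) + 1
    return sentence_from_mention(tokens, mention), mention


def generate_corpus(
    config: SynthConfig, resources: SynthResources | None = None
) -> tuple[list[AnnotatedSentence], list[EventMention], SynthResources]:
    """Generate a fully annotated corpus; byte-reproducible from the seed."""
    if resources is None:
        resources = build_resources(config)
    rng = np.random.default_rng(config.seed + 1)
    categories = list(config.category_proportions)
    probs = np.array([config.category_proportions[c] for c in categories])
    sentences, mentions = [], []
    for _ in range(config.n_mentions):
        category = categories[int(rng.choice(len(categories), p=probs))]
        sent, mention = generate_sentence(category, resources, config, rng)
        sentences.append(sent)
        mentions.append(mention)
    return sentences, mentions, resources
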
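"""Precision/recall/F1 scoring and the few-shot fivefold protocol.

All matching is strict: an element is correct only when label and both
boundaries agree, an arc only when dependent start, head start and the
event-qualified relation label agree.  Fold splitting stratifies by event
category and trains on one fifth, testing on the remaining four.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np

from .schema import AnnotatedSentence, EventMention, SchemaError, Span


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other: "EvalCounts"):
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def prf(counts: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall and F1; zero denominators yield 0 by convention."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class EvalReport:
    per_label: dict[str, EvalCounts] = field(default_factory=dict)

    def counts(self, label: str) -> EvalCounts:
        return self.per_label.setdefault(label, EvalCounts())

    @property
    def micro(self) -> EvalCounts:
        total = EvalCounts()
        for c in self.per_label.values():
            total += c
        return total

    def micro_prf(self) -> tuple[float, float, float]:
        return prf(self.micro)

    def macro_f1(self) -> float:
        if not self.per_label:
            return 0.0
        return float(np.mean([prf(c)[2] for c in self.per_label.values()]))

    def merge(self, other: "EvalReport") -> "EvalReport":
        for label, c in other.per_label.items():
            self.counts(label).__iadd__(c)
        return self

    def to_dict(self) -> dict:
        out: dict = {"labels": {}}
        for label, c in sorted(self.per_label.items()):
            p, r, f1 = prf(c)
            out["labels"][label] = {
                "tp": c.tp, "fp": c.fp, "fn": c.fn, "P": p, "R": r, "F1": f1,
            }
        mp, mr, mf = self.micro_prf()
        out["micro"] = {"P": mp, "R": mr, "F1": mf}
        out["macro_F1"] = self.macro_f1()
        return out

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _score_sets(
    predicted: Iterable[Sequence[Hashable]],
    gold: Iterable[Sequence[Hashable]],
    label_of: Callable[[Hashable], str],
) -> EvalReport:
    report = EvalReport()
    for pred_set, gold_set in zip(predicted, gold, strict=True):
        pred_set, gold_set = set(pred_set), set(gold_set)
        for item in pred_set & gold_set:
            report.counts(label_of(item)).tp += 1
        for item in pred_set - gold_set:
            report.counts(label_of(item)).fp += 1
        for item in gold_set - pred_set:
            report.counts(label_of(item)).fn += 1
    return report


def score_elements(
    predicted: Sequence[Iterable[Span]], gold: Sequence[Iterable[Span]]
) -> EvalReport:
    """Strict span scoring, per element label, over parallel sentence lists."""
    to_tuple = lambda spans: {(s.start, s.end, s.label) for s in spans}
    return _score_sets(
        [to_tuple(p) for p in predicted],
        [to_tuple(g) for g in gold],
        label_of=lambda item: item[2],
    )


def score_links(
    predicted: Sequence[Iterable[tuple[int, int, str]]],
    gold: Sequence[Iterable[tuple[int, int, str]]],
) -> EvalReport:
    """Strict arc scoring, per event-qualified relation label."""
    return _score_sets(predicted, gold, label_of=lambda item: item[2])


def _event_key(mention: EventMention, mode: str):
    trigger = (mention.trigger.start, mention.trigger.end, mention.category)
    if mode == "relaxed":
        return trigger
    links = frozenset(
        (role, sp.start, sp.end, sp.label) for role, sp in mention.role_links
    )
    return trigger + (links,)


def score_events(
    predicted: Sequence[Iterable[EventMention]],
    gold: Sequence[Iterable[EventMention]],
    mode: str = "strict",
) -> EvalReport:
    """Event-level scoring: strict also requires the exact role-link set."""
    if mode not in ("strict", "relaxed"):
        raise SchemaError(f"unknown event scoring mode {mode!r}")
    return _score_sets(
        [{_event_key(m, mode) for m in p} for p in predicted],
        [{_event_key(m, mode) for m in g} for g in gold],
        label_of=lambda item: item[2],
    )


def fivefold_split(
    corpus: Sequence[AnnotatedSentence],
    categories: Sequence[str],
    seed: int,
) -> list[tuple[list[int], list[int]]]:
    """Category-stratified fivefold few-shot splits.

    Each category's items are shuffled and divided into five near-equal
    parts; fold i trains on part i and tests on the remaining four.
    Returns (train indices, test indices) per fold.
    """
    if len(corpus) != len(categories):
        raise SchemaError("corpus and category labels must be parallel")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in range(5)]
    for category in sorted(set(categories)):
        idx = [i for i, c in enumerate(categories) if c == category]
        if len(idx) < 5:
            raise SchemaError(
                f"category {category!r} has {len(idx)} mentions; "
                "at least 5 are required for fivefold splitting"
            )
        idx = [idx[i] for i in rng.permutation(len(idx))]
        for k, chunk in enumerate(np.array_split(idx, 5)):
            parts[k].extend(int(i) for i in chunk)
    folds = []
    for k in range(5):
        train = sorted(parts[k])
        test = sorted(i for j in range(5) if j != k for i in parts[j])
        folds.append((train, test))
    return folds
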
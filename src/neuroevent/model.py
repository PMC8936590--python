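"""Joint event extraction network.

A stacked BiLSTM encoder feeds (a) a per-token element scorer with a
linear-chain CRF over the 37 BIO tags and (b) a multi-label head-selection
scorer over the 18 relation labels.  The two losses are summed into the
joint training objective.  Everything runs on the package's own autodiff
engine; no external deep-learning framework is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, bce_with_logits, concat, parameter, stack
from .bootstrap import DictionarySet
from .features import EmbeddingTable, FeatureConfig, featurize_sentence
from .schema import (
    ABBREV_TO_EVENT,
    ATTRIBUTE_CODES,
    ATTRIBUTE_HOST,
    ELEMENT_TAGS,
    ELEMENT_TAG_INDEX,
    EVENT_SLOTS,
    NONE_RELATION,
    RELATION_INDEX,
    RELATION_LABELS,
    AnnotatedSentence,
    EventMention,
    SchemaError,
    Span,
    Token,
    decode_bio,
    decode_mentions,
    validate_event,
)

N_TAGS = len(ELEMENT_TAGS)
N_RELATIONS = len(RELATION_LABELS)
NONE_IDX = RELATION_INDEX[NONE_RELATION]


@dataclass
class ModelConfig:
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    hidden_size: int = 64  # d, per direction
    num_layers: int = 3
    scorer_width: int = 64  # l
    dropout_keep: float = 0.9  # keep probability between LSTM layers
    threshold: float = 0.5  # relation decoding threshold
    lr: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    #: reset the optimizer's moment estimates every this many epochs
    #: (0 disables warm restarts)
    restart_every: int = 0


@dataclass
class LossReport:
    l_ner: float
    l_rar: float

    @property
    def l_joint(self) -> float:
        return self.l_ner + self.l_rar


# --------------------------------------------------------------------------
# encoder
# --------------------------------------------------------------------------


class _LSTMDirection:
    def __init__(self, input_dim: int, d: int, rng: np.random.Generator,
                 input_scale: np.ndarray | None = None):
        k = 1.0 / np.sqrt(max(input_dim, 1))
        wx = rng.uniform(-k, k, size=(input_dim, 4 * d))
        if input_scale is not None:
            wx *= input_scale[:, None]
        kh = 1.0 / np.sqrt(d)
        wh = rng.uniform(-kh, kh, size=(d, 4 * d))
        b = np.zeros(4 * d)
        b[d : 2 * d] = 1.0  # forget-gate bias
        self.wx, self.wh, self.b = parameter(wx), parameter(wh), parameter(b)
        self.d = d

    def params(self):
        return [self.wx, self.wh, self.b]

    def run(self, x: Tensor, mask: np.ndarray, reverse: bool) -> list[Tensor]:
        batch, T = mask.shape
        d = self.d
        # project all timesteps at once; the recurrence only adds h @ Wh
        xz = x @ self.wx + self.b
        h = Tensor(np.zeros((batch, d)))
        c = Tensor(np.zeros((batch, d)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        out: dict[int, Tensor] = {}
        for t in order:
            z = xz[:, t, :] + h @ self.wh
            i = z[:, 0:d].sigmoid()
            f = z[:, d : 2 * d].sigmoid()
            g = z[:, 2 * d : 3 * d].tanh()
            o = z[:, 3 * d : 4 * d].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = mask[:, t : t + 1]
            if m.all():
                h, c = h_new, c_new
            else:
                h = m * h_new + (1.0 - m) * h
                c = m * c_new + (1.0 - m) * c
            out[t] = h
        return [out[t] for t in range(T)]


class BiLSTMEncoder:
    """Stacked bidirectional LSTM producing 2d-wide token representations."""

    def __init__(self, config: ModelConfig, input_dim: int, rng: np.random.Generator):
        self.config = config
        d = config.hidden_size
        # the raw terminology index (last input dim) spans 0..36; damp its
        # initial weights so it does not saturate the gates at step one
        scale = np.ones(input_dim)
        scale[-1] = 1.0 / N_TAGS
        self.layers: list[tuple[_LSTMDirection, _LSTMDirection]] = []
        for layer in range(config.num_layers):
            in_dim = input_dim if layer == 0 else 2 * d
            sc = scale if layer == 0 else None
            self.layers.append(
                (_LSTMDirection(in_dim, d, rng, sc), _LSTMDirection(in_dim, d, rng, sc))
            )

    def params(self):
        out = []
        for fwd, bwd in self.layers:
            out += fwd.params() + bwd.params()
        return out

    def encode(self, x: Tensor, mask: np.ndarray,
               dropout_masks: list[np.ndarray] | None = None) -> Tensor:
        """Encode a padded (B, T, F) batch into (B, T, 2d) states."""
        if x.shape[1] == 0:
            raise SchemaError("cannot encode an empty sentence")
        T = x.shape[1]
        for li, (fwd, bwd) in enumerate(self.layers):
            hf = fwd.run(x, mask, reverse=False)
            hb = bwd.run(x, mask, reverse=True)
            x = stack([concat([hf[t], hb[t]], axis=1) for t in range(T)], axis=1)
            if dropout_masks is not None and li < len(self.layers) - 1:
                x = x * dropout_masks[li]
        return x


# --------------------------------------------------------------------------
# element scorer + CRF
# --------------------------------------------------------------------------


class ElementScorer:
    """Per-token tag scores: V . f(U h_i) with tanh activation."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        two_d, l = 2 * config.hidden_size, config.scorer_width
        self.u = parameter(rng.uniform(-1, 1, size=(two_d, l)) / np.sqrt(two_d))
        self.v = parameter(rng.uniform(-1, 1, size=(l, N_TAGS)) / np.sqrt(l))

    def params(self):
        return [self.u, self.v]

    def emissions(self, h: Tensor) -> Tensor:
        return (h @ self.u).tanh() @ self.v


class LinearChainCRF:
    """Sequence-level CRF: emission + transition scores, forward log-partition."""

    def __init__(self, n_tags: int = N_TAGS, rng: np.random.Generator | None = None):
        self.n_tags = n_tags
        init = np.zeros((n_tags, n_tags))
        if rng is not None:
            init = rng.uniform(-0.01, 0.01, size=(n_tags, n_tags))
        self.transitions = parameter(init)

    def params(self):
        return [self.transitions]

    def loglik(self, emissions: Tensor, tags: np.ndarray, mask: np.ndarray) -> Tensor:
        """Per-sentence log-likelihood of the gold tag sequences, shape (B,)."""
        B, T, K = emissions.shape
        if tags.shape != (B, T):
            raise SchemaError("gold tags must match emissions batch shape")
        if tags.min() < 0 or tags.max() >= K:
            raise SchemaError("gold tag outside the label set")
        onehot = np.zeros((B, T, K))
        onehot[np.arange(B)[:, None], np.arange(T)[None, :], tags] = 1.0
        onehot *= mask[:, :, None]
        em_score = (emissions * onehot).sum(axis=(1, 2))
        pair = np.zeros((B, K, K))
        for t in range(1, T):
            active = mask[:, t] > 0
            rows = np.nonzero(active)[0]
            np.add.at(pair, (rows, tags[rows, t - 1], tags[rows, t]), 1.0)
        tr_score = (self.transitions.reshape(1, K, K) * pair).sum(axis=(1, 2))
        logz = self._log_partition(emissions, mask)
        return em_score + tr_score - logz

    def _log_partition(self, emissions: Tensor, mask: np.ndarray) -> Tensor:
        B, T, K = emissions.shape
        alpha = emissions[:, 0, :]
        for t in range(1, T):
            step = (
                alpha.reshape(B, K, 1) + self.transitions.reshape(1, K, K)
            ).logsumexp(axis=1) + emissions[:, t, :]
            m = mask[:, t : t + 1]
            alpha = m * step + (1.0 - m) * alpha
        return alpha.logsumexp(axis=1)

    def decode(self, emissions: np.ndarray) -> list[int]:
        """Viterbi decoding of one sentence; ties break to the lowest index."""
        T, K = emissions.shape
        trans = self.transitions.data
        dp = emissions[0].copy()
        back = np.zeros((T, K), dtype=int)
        for t in range(1, T):
            scores = dp[:, None] + trans  # (prev, cur)
            back[t] = scores.argmax(axis=0)
            dp = scores.max(axis=0) + emissions[t]
        path = [int(dp.argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        return path[::-1]


# --------------------------------------------------------------------------
# head selection
# --------------------------------------------------------------------------


class HeadSelector:
    """Pairwise relation logits: V_r . f(U h_i + W h_j) for every (i, j, r)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        two_d, l = 2 * config.hidden_size, config.scorer_width
        self.u = parameter(rng.uniform(-1, 1, size=(two_d, l)) / np.sqrt(two_d))
        self.w = parameter(rng.uniform(-1, 1, size=(two_d, l)) / np.sqrt(two_d))
        self.v = parameter(rng.uniform(-1, 1, size=(l, N_RELATIONS)) / np.sqrt(l))

    def params(self):
        return [self.u, self.w, self.v]

    def logits(self, h: Tensor) -> Tensor:
        """(B, T, T, R) scores; [b, i, j, r] scores token j as head of i."""
        B, T, _ = h.shape
        l = self.u.shape[1]
        a = (h @ self.u).reshape(B, T, 1, l)
        b = (h @ self.w).reshape(B, 1, T, l)
        return (a + b).tanh() @ self.v


def head_score(selector: HeadSelector, h_i: np.ndarray, h_j: np.ndarray,
               relation: int) -> float:
    """Scalar score for one (dependent, head, relation) triple."""
    hidden = np.tanh(selector.u.data.T @ h_i + selector.w.data.T @ h_j)
    return float(selector.v.data[:, relation] @ hidden)


def decode_links(probs: np.ndarray, threshold: float = 0.5) -> set[tuple[int, int, str]]:
    """All (dependent, head, label) arcs with probability above the threshold.

    Positions are 1-based; arcs labeled "none" are dropped.
    """
    if not (0.0 < threshold < 1.0):
        raise SchemaError("decoding threshold must lie in (0, 1)")
    arcs = set()
    for i, j, k in zip(*np.nonzero(probs > threshold)):
        label = RELATION_LABELS[k]
        if label == NONE_RELATION:
            continue
        arcs.add((int(i) + 1, int(j) + 1, label))
    return arcs


# --------------------------------------------------------------------------
# gold structures
# --------------------------------------------------------------------------


def gold_arcs(sentence: AnnotatedSentence) -> set[tuple[int, int, str]]:
    """(dependent start, head start, relation) arcs of a sentence's mentions.

    Role arcs point argument -> trigger, attribute arcs point attribute ->
    argument.  Links whose event-qualified label is outside the relation
    set are skipped.
    """
    arcs = set()
    for mention in decode_mentions(sentence):
        for role, sp in mention.role_links:
            label = f"{mention.category}-{role}"
            if label in RELATION_INDEX:
                arcs.add((sp.start, mention.trigger.start, label))
        for arg, attr in mention.attribute_links:
            label = f"{arg.label}-attribute"
            if label in RELATION_INDEX:
                arcs.add((attr.start, arg.start, label))
    return arcs


def arc_targets(sentence: AnnotatedSentence, T: int) -> np.ndarray:
    """Multi-hot (T, T, R) target tensor; headless tokens self-select "none"."""
    n = len(sentence.tokens)
    y = np.zeros((T, T, N_RELATIONS))
    has_head = np.zeros(n, dtype=bool)
    for i, j, label in gold_arcs(sentence):
        y[i - 1, j - 1, RELATION_INDEX[label]] = 1.0
        has_head[i - 1] = True
    for i in range(n):
        if not has_head[i]:
            y[i, i, NONE_IDX] = 1.0
    return y


# --------------------------------------------------------------------------
# the joint model
# --------------------------------------------------------------------------


@dataclass
class Batch:
    x: np.ndarray  # (B, T, F)
    mask: np.ndarray  # (B, T)
    tags: np.ndarray  # (B, T) int
    arcs: np.ndarray  # (B, T, T, R)
    lengths: list[int]


class JointEventModel:
    def __init__(self, config: ModelConfig, embeddings: EmbeddingTable,
                 dicts: DictionarySet):
        self.config = config
        self.embeddings = embeddings
        self.dicts = dicts
        rng = np.random.default_rng(config.seed)
        self.encoder = BiLSTMEncoder(config, config.feature.total_dim, rng)
        self.scorer = ElementScorer(config, rng)
        self.crf = LinearChainCRF(N_TAGS, rng)
        self.head = HeadSelector(config, rng)

    def params(self) -> list[Tensor]:
        return (
            self.encoder.params()
            + self.scorer.params()
            + self.crf.params()
            + self.head.params()
        )

    # ---- data preparation ----------------------------------------------

    def featurize(self, tokens: Sequence[Token]) -> np.ndarray:
        return featurize_sentence(
            tokens, self.embeddings, self.dicts, self.config.feature
        )

    def make_batch(self, sentences: Sequence[AnnotatedSentence]) -> Batch:
        feats = [self.featurize(s.tokens) for s in sentences]
        B = len(sentences)
        T = max(f.shape[0] for f in feats)
        F = feats[0].shape[1]
        x = np.zeros((B, T, F))
        mask = np.zeros((B, T))
        tags = np.zeros((B, T), dtype=int)
        arcs = np.zeros((B, T, T, N_RELATIONS))
        lengths = []
        for b, (sent, f) in enumerate(zip(sentences, feats)):
            n = f.shape[0]
            x[b, :n] = f
            mask[b, :n] = 1.0
            tags[b, :n] = [ELEMENT_TAG_INDEX[t] for t in sent.element_tags]
            arcs[b] = arc_targets(sent, T)
            lengths.append(n)
        return Batch(x, mask, tags, arcs, lengths)

    # ---- losses ---------------------------------------------------------

    def loss(self, batch: Batch, x: Tensor | None = None,
             dropout_masks: list[np.ndarray] | None = None) -> tuple[Tensor, LossReport]:
        """Joint loss (mean per sentence) on a batch; ``x`` overrides inputs."""
        if x is None:
            x = Tensor(batch.x)
        B = batch.x.shape[0]
        h = self.encoder.encode(x, batch.mask, dropout_masks)
        emissions = self.scorer.emissions(h)
        loglik = self.crf.loglik(emissions, batch.tags, batch.mask)
        l_ner = -loglik.sum() * (1.0 / B)
        logits = self.head.logits(h)
        pair_mask = (batch.mask[:, :, None] * batch.mask[:, None, :])[..., None]
        l_rar = bce_with_logits(logits, batch.arcs, pair_mask) * (1.0 / B)
        total = l_ner + l_rar
        return total, LossReport(float(l_ner.data), float(l_rar.data))

    def dropout_masks(self, batch: Batch, rng: np.random.Generator) -> list[np.ndarray] | None:
        keep = self.config.dropout_keep
        if keep >= 1.0 or self.config.num_layers < 2:
            return None
        B, T = batch.mask.shape
        d2 = 2 * self.config.hidden_size
        return [
            (rng.random((B, T, d2)) < keep).astype(float) / keep
            for _ in range(self.config.num_layers - 1)
        ]

    # ---- prediction -----------------------------------------------------

    def forward_scores(self, sentences: Sequence[Sequence[Token]]):
        """Emission scores and arc probabilities for raw token sequences."""
        feats = [self.featurize(toks) for toks in sentences]
        B = len(feats)
        T = max(f.shape[0] for f in feats)
        x = np.zeros((B, T, feats[0].shape[1]))
        mask = np.zeros((B, T))
        for b, f in enumerate(feats):
            x[b, : f.shape[0]] = f
            mask[b, : f.shape[0]] = 1.0
        h = self.encoder.encode(Tensor(x), mask)
        emissions = self.scorer.emissions(h).data
        probs = 1.0 / (1.0 + np.exp(-self.head.logits(h).data))
        return emissions, probs, mask

    def predict_events(
        self, sentences: Sequence[Sequence[Token]]
    ) -> list[list[tuple[EventMention, list[str]]]]:
        """Decode each sentence into (mention, violations) pairs."""
        if not sentences:
            return []
        emissions, probs, mask = self.forward_scores(sentences)
        out = []
        for b, toks in enumerate(sentences):
            n = len(toks)
            tag_idx = self.crf.decode(emissions[b, :n])
            tags = [ELEMENT_TAGS[i] for i in tag_idx]
            arcs = decode_links(probs[b, :n, :n], self.config.threshold)
            out.append(assemble_events(tags, arcs))
        return out


def assemble_events(
    tags: Sequence[str], arcs: set[tuple[int, int, str]]
) -> list[tuple[EventMention, list[str]]]:
    """Compose decoded tags and arcs into one mention per predicted trigger.

    Arcs that are incompatible with the schema (wrong event category for the
    relation, endpoints that are not span starts, inadmissible argument
    category) are discarded.
    """
    spans = decode_bio(tags)
    by_start = {sp.start: sp for sp in spans}
    triggers = [sp for sp in spans if sp.label in ABBREV_TO_EVENT]
    mentions = []
    for trig in triggers:
        category = ABBREV_TO_EVENT[trig.label]
        slot_by_role = {s.role: s for s in EVENT_SLOTS[category]}
        role_links = []
        linked: dict[int, Span] = {}
        for i, j, label in sorted(arcs):
            if j != trig.start or "-" not in label:
                continue
            event, role = label.rsplit("-", 1)
            if event != category or role not in slot_by_role:
                continue
            dep = by_start.get(i)
            if dep is None or dep.label not in slot_by_role[role].categories:
                continue
            role_links.append((role, dep))
            linked[dep.start] = dep
        attribute_links = []
        for i, j, label in sorted(arcs):
            event, _, role = label.rpartition("-")
            if role != "attribute":
                continue
            host = linked.get(j)
            dep = by_start.get(i)
            if host is None or dep is None:
                continue
            if dep.label not in ATTRIBUTE_CODES or ATTRIBUTE_HOST[dep.label] != host.label:
                continue
            attribute_links.append((host, dep))
        mention = EventMention(category, trig, role_links, attribute_links)
        mentions.append((mention, validate_event(mention)))
    return mentions


# --------------------------------------------------------------------------
# plain joint training
# --------------------------------------------------------------------------


def make_batches(model: JointEventModel, sentences: Sequence[AnnotatedSentence],
                 batch_size: int) -> list[Batch]:
    return [
        model.make_batch(sentences[i : i + batch_size])
        for i in range(0, len(sentences), batch_size)
    ]


def train_joint(
    model: JointEventModel,
    corpus: Sequence[AnnotatedSentence],
    epochs: int,
    rng: np.random.Generator | None = None,
    record: list[LossReport] | None = None,
) -> list[LossReport]:
    """Minimize the joint loss with Adam; returns per-step loss reports."""
    rng = rng or np.random.default_rng(model.config.seed)
    optimizer = ad.Adam(model.params(), lr=model.config.lr)
    trace = record if record is not None else []
    corpus = list(corpus)
    restart = model.config.restart_every
    for epoch in range(epochs):
        if restart > 0 and epoch > 0 and epoch % restart == 0:
            optimizer.reset_state()
        order = rng.permutation(len(corpus))
        batches = make_batches(
            model, [corpus[i] for i in order], model.config.batch_size
        )
        for batch in batches:
            dropout = model.dropout_masks(batch, rng)
            total, report = model.loss(batch, dropout_masks=dropout)
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            trace.append(report)
    return trace


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

_PARAM_ORDER = "encoder/scorer/crf/head parameters in declaration order"


def save_model(model: JointEventModel, path_prefix: str) -> None:
    arrays = {f"p{i}": p.data for i, p in enumerate(model.params())}
    np.savez(f"{path_prefix}.npz", **arrays)
    sidecar = {
        "config": {
            **{k: v for k, v in asdict(model.config).items() if k != "feature"},
            "feature": asdict(model.config.feature),
        },
        "element_tags": list(ELEMENT_TAGS),
        "relation_labels": list(RELATION_LABELS),
        "embedding": {"dim": model.embeddings.dim, "seed": model.embeddings.seed},
        "dictionaries": {
            cat: [" ".join(t) for t in terms]
            for cat, terms in model.dicts.entries.items()
        },
        "param_order": _PARAM_ORDER,
    }
    with open(f"{path_prefix}.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path_prefix: str) -> JointEventModel:
    with open(f"{path_prefix}.json", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    cfg_raw = dict(sidecar["config"])
    feature = FeatureConfig(**cfg_raw.pop("feature"))
    config = ModelConfig(feature=feature, **cfg_raw)
    emb = sidecar["embedding"]
    if emb.get("seed") is None:
        raise SchemaError("checkpoint lacks a reconstructible embedding table")
    embeddings = EmbeddingTable.seeded(emb["dim"], emb["seed"])
    dicts = DictionarySet.from_strings(sidecar["dictionaries"])
    model = JointEventModel(config, embeddings, dicts)
    data = np.load(f"{path_prefix}.npz")
    for i, p in enumerate(model.params()):
        p.data = data[f"p{i}"]
    return model
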
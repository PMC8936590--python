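import itertools

import numpy as np
import pytest

from neuroevent import autodiff as ad
from neuroevent.autodiff import Tensor, parameter
from neuroevent.features import EmbeddingTable, FeatureConfig
from neuroevent.model import (
    Batch,
    JointEventModel,
    LinearChainCRF,
    LossReport,
    ModelConfig,
    arc_targets,
    assemble_events,
    decode_links,
    gold_arcs,
    head_score,
    load_model,
    make_batches,
    save_model,
    train_joint,
)
from neuroevent.schema import (
    ELEMENT_TAGS,
    NONE_RELATION,
    RELATION_INDEX,
    RELATION_LABELS,
    SchemaError,
    Span,
)

SMALL_CONFIG = ModelConfig(
    hidden_size=8, num_layers=1, scorer_width=8, batch_size=4,
    dropout_keep=1.0, seed=3,
)


@pytest.fixture
def small_model(small_corpus, embeddings):
    _, _, resources = small_corpus
    return JointEventModel(SMALL_CONFIG, embeddings, resources.dicts)


# --------------------------------------------------------------------------
# encoder
# --------------------------------------------------------------------------


class TestEncoder:
    def test_output_shape(self, small_model):
        x = Tensor(np.random.default_rng(0).normal(size=(2, 6, 33)))
        mask = np.ones((2, 6))
        h = small_model.encoder.encode(x, mask)
        assert h.shape == (2, 6, 16)  # 2d with d=8

    def test_reference_dimensions(self, small_corpus, embeddings):
        _, _, resources = small_corpus
        config = ModelConfig(hidden_size=64, num_layers=1, scorer_width=16)
        model = JointEventModel(config, embeddings, resources.dicts)
        x = Tensor(np.zeros((1, 5, 33)))
        h = model.encoder.encode(x, np.ones((1, 5)))
        assert h.shape == (1, 5, 128)

    def test_single_token(self, small_model):
        h = small_model.encoder.encode(Tensor(np.zeros((1, 1, 33))), np.ones((1, 1)))
        assert h.shape == (1, 1, 16)

    def test_empty_rejected(self, small_model):
        with pytest.raises(SchemaError):
            small_model.encoder.encode(Tensor(np.zeros((1, 0, 33))), np.ones((1, 0)))

    def test_deterministic(self, small_model):
        x = np.random.default_rng(5).normal(size=(2, 4, 33))
        mask = np.ones((2, 4))
        a = small_model.encoder.encode(Tensor(x), mask).data
        b = small_model.encoder.encode(Tensor(x), mask).data
        np.testing.assert_array_equal(a, b)

    def test_padding_does_not_change_prefix(self, small_model):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 4, 33))
        padded = np.zeros((1, 6, 33))
        padded[:, :4] = x
        mask = np.zeros((1, 6))
        mask[:, :4] = 1
        short = small_model.encoder.encode(Tensor(x), np.ones((1, 4))).data
        long = small_model.encoder.encode(Tensor(padded), mask).data
        np.testing.assert_allclose(short, long[:, :4], atol=1e-12)


# --------------------------------------------------------------------------
# CRF with enumeration oracles
# --------------------------------------------------------------------------


def enumerate_scores(emissions: np.ndarray, trans: np.ndarray):
    """Score of every tag sequence by brute force."""
    T, K = emissions.shape
    out = {}
    for seq in itertools.product(range(K), repeat=T):
        s = sum(emissions[t, y] for t, y in enumerate(seq))
        s += sum(trans[seq[t - 1], seq[t]] for t in range(1, T))
        out[seq] = s
    return out


class TestCRF:
    def _crf(self, K, rng):
        crf = LinearChainCRF(K)
        crf.transitions.data = rng.normal(size=(K, K))
        return crf

    def test_uniform_scores_closed_form(self):
        K, T = 4, 3
        crf = LinearChainCRF(K)
        crf.transitions.data = np.zeros((K, K))
        emissions = Tensor(np.zeros((1, T, K)))
        tags = np.zeros((1, T), dtype=int)
        loglik = crf.loglik(emissions, tags, np.ones((1, T)))
        assert abs(loglik.data[0] - (-T * np.log(K))) < 1e-12

    def test_single_token_logsumexp(self, rng):
        K = 5
        crf = LinearChainCRF(K)
        em = rng.normal(size=(1, 1, K))
        loglik = crf.loglik(Tensor(em), np.array([[2]]), np.ones((1, 1)))
        want = em[0, 0, 2] - np.log(np.exp(em[0, 0]).sum())
        assert abs(loglik.data[0] - want) < 1e-12

    def test_matches_enumeration_200_instances(self, rng):
        for _ in range(200):
            K = int(rng.integers(1, 5))
            T = int(rng.integers(1, 6))
            crf = self._crf(K, rng)
            em = rng.normal(size=(T, K))
            gold = rng.integers(0, K, size=T)
            scores = enumerate_scores(em, crf.transitions.data)
            logz = np.logaddexp.reduce(np.array(list(scores.values())))
            want = scores[tuple(gold)] - logz
            got = crf.loglik(
                Tensor(em[None]), gold[None], np.ones((1, T))
            ).data[0]
            assert abs(got - want) < 1e-6
            # Viterbi equals enumeration argmax with lowest-index ties
            best = min(scores, key=lambda s: (-scores[s], s))
            assert tuple(crf.decode(em)) == best

    def test_normalization_sums_to_one(self, rng):
        K, T = 3, 4
        crf = self._crf(K, rng)
        em = rng.normal(size=(T, K))
        scores = enumerate_scores(em, crf.transitions.data)
        logz = np.logaddexp.reduce(np.array(list(scores.values())))
        total = sum(np.exp(s - logz) for s in scores.values())
        assert abs(total - 1.0) < 1e-6

    def test_decoded_score_at_least_gold(self, rng):
        for _ in range(50):
            K, T = 4, 5
            crf = self._crf(K, rng)
            em = rng.normal(size=(T, K))
            scores = enumerate_scores(em, crf.transitions.data)
            decoded = tuple(crf.decode(em))
            gold = tuple(rng.integers(0, K, size=T))
            assert scores[decoded] >= scores[gold] - 1e-12

    def test_single_tag_decoding(self):
        crf = LinearChainCRF(1)
        assert crf.decode(np.zeros((4, 1))) == [0, 0, 0, 0]

    def test_tag_outside_label_set_rejected(self):
        crf = LinearChainCRF(3)
        with pytest.raises(SchemaError):
            crf.loglik(Tensor(np.zeros((1, 2, 3))), np.array([[0, 7]]), np.ones((1, 2)))

    def test_batch_matches_per_sentence(self, rng):
        K = 3
        crf = self._crf(K, rng)
        lengths = [2, 4]
        T = max(lengths)
        em = rng.normal(size=(2, T, K))
        mask = np.zeros((2, T))
        tags = np.zeros((2, T), dtype=int)
        for b, n in enumerate(lengths):
            mask[b, :n] = 1
            tags[b, :n] = rng.integers(0, K, size=n)
        batched = crf.loglik(Tensor(em), tags, mask).data
        for b, n in enumerate(lengths):
            single = crf.loglik(
                Tensor(em[b : b + 1, :n]), tags[b : b + 1, :n], np.ones((1, n))
            ).data[0]
            assert abs(batched[b] - single) < 1e-10


# --------------------------------------------------------------------------
# head selection
# --------------------------------------------------------------------------


class TestHeadSelection:
    def test_zero_v_gives_half_probability(self, small_model):
        small_model.head.v.data[:] = 0.0
        h = Tensor(np.random.default_rng(0).normal(size=(1, 3, 16)))
        logits = small_model.head.logits(h).data
        np.testing.assert_array_equal(logits, np.zeros_like(logits))
        probs = 1 / (1 + np.exp(-logits))
        np.testing.assert_array_equal(probs, np.full_like(probs, 0.5))

    def test_matches_direct_formula(self, small_model, rng):
        h = rng.normal(size=(2, 4, 16))
        logits = small_model.head.logits(Tensor(h)).data
        for b in range(2):
            for i in range(4):
                for j in range(4):
                    for k in range(len(RELATION_LABELS)):
                        want = head_score(small_model.head, h[b, i], h[b, j], k)
                        assert abs(logits[b, i, j, k] - want) < 1e-10

    def test_probability_monotone_in_score(self):
        s = np.linspace(-4, 4, 9)
        p = 1 / (1 + np.exp(-s))
        assert np.all(np.diff(p) > 0)


class TestDecodeLinks:
    def test_thresholding(self):
        probs = np.zeros((9, 9, len(RELATION_LABELS)))
        produces = RELATION_INDEX["Acquisition-produces"]
        from_rel = RELATION_INDEX["Acquisition-uses"]
        uses = RELATION_INDEX["PerformAnalysis-uses"]
        probs[2, 4, produces] = 0.9
        probs[7, 4, from_rel] = 0.6
        probs[1, 4, uses] = 0.3
        arcs = decode_links(probs, 0.5)
        assert arcs == {
            (3, 5, "Acquisition-produces"), (8, 5, "Acquisition-uses"),
        }

    def test_all_below_threshold(self):
        probs = np.full((3, 3, len(RELATION_LABELS)), 0.2)
        assert decode_links(probs, 0.5) == set()

    def test_none_arcs_dropped(self):
        probs = np.zeros((2, 2, len(RELATION_LABELS)))
        probs[0, 0, RELATION_INDEX[NONE_RELATION]] = 0.99
        assert decode_links(probs, 0.5) == set()

    def test_equals_brute_force_filter(self, rng):
        probs = rng.random((5, 5, len(RELATION_LABELS)))
        arcs = decode_links(probs, 0.5)
        want = set()
        for i in range(5):
            for j in range(5):
                for k, label in enumerate(RELATION_LABELS):
                    if probs[i, j, k] > 0.5 and label != NONE_RELATION:
                        want.add((i + 1, j + 1, label))
        assert arcs == want

    def test_bad_threshold_rejected(self):
        with pytest.raises(SchemaError):
            decode_links(np.zeros((1, 1, 18)), 1.5)


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------


class TestLosses:
    def test_rar_loss_zero_at_perfect_fit(self):
        from neuroevent.autodiff import bce_with_logits

        targets = np.zeros((1, 2, 2, 2))
        targets[0, 0, 1, 0] = 1.0
        logits = Tensor(np.where(targets > 0, 500.0, -500.0))
        loss = bce_with_logits(logits, targets, np.ones_like(targets))
        assert loss.data < 1e-12

    def test_rar_loss_manual_two_tokens(self):
        from neuroevent.autodiff import bce_with_logits

        # 2 tokens, 2 relations: manually computed BCE
        logits = np.array([[[[0.5, -0.5], [1.0, 0.0]],
                            [[-1.0, 2.0], [0.0, 0.3]]]])
        targets = np.zeros_like(logits)
        targets[0, 0, 1, 0] = 1.0
        targets[0, 1, 1, 1] = 1.0
        p = 1 / (1 + np.exp(-logits))
        manual = -(targets * np.log(p) + (1 - targets) * np.log(1 - p)).sum()
        got = bce_with_logits(Tensor(logits), targets, np.ones_like(logits)).data
        assert abs(got - manual) < 1e-10

    def test_joint_loss_is_sum(self):
        report = LossReport(l_ner=1.5, l_rar=2.25)
        assert report.l_joint == 3.75
        assert LossReport(0.0, 0.0).l_joint == 0.0
        assert LossReport(4.0, 0.0).l_joint == 4.0

    def test_loss_nonnegative_on_batch(self, small_model, small_corpus):
        sentences, _, _ = small_corpus
        batch = small_model.make_batch(sentences[:4])
        total, report = small_model.loss(batch)
        assert report.l_ner >= 0.0 and report.l_rar >= 0.0
        assert abs(total.data - report.l_joint) < 1e-12


# --------------------------------------------------------------------------
# gold arc construction
# --------------------------------------------------------------------------


class TestGoldArcs:
    def test_arcs_point_to_trigger(self, small_corpus):
        sentences, mentions, _ = small_corpus
        for sent, mention in zip(sentences, mentions):
            arcs = gold_arcs(sent)
            role_arcs = {a for a in arcs if not a[2].endswith("-attribute")}
            assert len(role_arcs) == len(mention.role_links)
            for dep, head, label in role_arcs:
                assert head == mention.trigger.start
                assert label.startswith(mention.category)

    def test_headless_tokens_self_select_none(self, small_corpus):
        sentences, _, _ = small_corpus
        sent = sentences[0]
        n = len(sent.tokens)
        y = arc_targets(sent, n)
        heads = {a[0] - 1 for a in gold_arcs(sent)}
        none_idx = RELATION_INDEX[NONE_RELATION]
        for i in range(n):
            if i not in heads:
                assert y[i, i, none_idx] == 1.0


# --------------------------------------------------------------------------
# event assembly
# --------------------------------------------------------------------------


class TestAssembleEvents:
    def test_oracle_scores_reproduce_worked_mention(self):
        tags = ["O", "B-ACQ_A", "B-AOB", "O", "B-Acq", "O", "O", "B-BRI", "I-BRI"]
        arcs = {
            (3, 5, "Acquisition-produces"),
            (2, 3, "ACQ-attribute"),
        }
        ((mention, violations),) = assemble_events(tags, arcs)
        assert mention.category == "Acquisition"
        assert mention.trigger == Span(5, 5, "Acq")
        assert [sp.start for _, sp in mention.role_links] == [3]
        # the ACQ-attribute arc is dropped: its head is an AOB argument
        assert mention.attribute_links == []

    def test_incompatible_relation_discarded(self):
        tags = ["B-Act", "B-COG", "B-BRI"]
        arcs = {
            (2, 1, "Activate-cause"),
            (3, 1, "Acquisition-uses"),  # wrong event for an Activate trigger
        }
        ((mention, _),) = assemble_events(tags, arcs)
        assert [r for r, _ in mention.role_links] == ["cause"]

    def test_no_trigger_no_mentions(self):
        assert assemble_events(["O", "B-BRI"], {(2, 1, "Activate-affect")}) == []

    def test_emitted_mentions_validated_or_flagged(self, rng):
        from neuroevent.schema import validate_event

        tags = ["B-Act", "B-COG", "B-BRI", "O"]
        arcs = {(2, 1, "Activate-cause"), (3, 1, "Activate-affect")}
        ((mention, violations),) = assemble_events(tags, arcs)
        assert violations == validate_event(mention)
        assert violations == []


# --------------------------------------------------------------------------
# prediction plumbing and training dynamics
# --------------------------------------------------------------------------


class TestPredictAndTrain:
    def test_predict_empty(self, small_model):
        assert small_model.predict_events([]) == []

    def test_training_loss_decreases(self, small_corpus, embeddings):
        sentences, _, resources = small_corpus
        config = ModelConfig(
            hidden_size=16, num_layers=1, scorer_width=16, batch_size=50,
            lr=1e-3, dropout_keep=1.0, seed=0,
        )
        model = JointEventModel(config, embeddings, resources.dicts)
        trace = train_joint(model, sentences[:50], epochs=21)
        losses = [r.l_joint for r in trace]
        # full-corpus batches: one step per epoch; strict decrease early on
        assert len(losses) >= 21
        for a, b in zip(losses[:20], losses[1:21]):
            assert b < a

    def test_identical_seeds_identical_training(self, small_corpus, embeddings):
        sentences, _, resources = small_corpus
        runs = []
        for _ in range(2):
            model = JointEventModel(SMALL_CONFIG, embeddings, resources.dicts)
            train_joint(model, sentences[:12], epochs=2)
            runs.append([p.data.copy() for p in model.params()])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip(self, small_model, small_corpus, tmp_path):
        sentences, _, _ = small_corpus
        train_joint(small_model, sentences[:8], epochs=1)
        prefix = str(tmp_path / "model")
        save_model(small_model, prefix)
        loaded = load_model(prefix)
        for a, b in zip(small_model.params(), loaded.params()):
            np.testing.assert_array_equal(a.data, b.data)
        toks = [sentences[0].tokens]
        a = small_model.forward_scores(toks)[0]
        b = loaded.forward_scores(toks)[0]
        np.testing.assert_array_equal(a, b)
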
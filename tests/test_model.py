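import math

import numpy as np
import pytest

from rolepred.corpus import Corpus
from rolepred.model import (
    EOS,
    Element,
    ModelConfig,
    SRPModel,
    elements_of,
    evaluate_role_accuracy,
    incremental_forward,
    kfold_evaluate,
    make_vocab,
    pretrain,
    train_main,
    training_loss,
)
from rolepred.synth import generate_adu_text, generate_cdu_corpus, load_preset

from conftest import make_utterance


@pytest.fixture
def small_model(fox_utterance):
    config = ModelConfig(seed=5, embedding_dim=8, encoder_hidden_dim=8,
                         processor_hidden_dim=10, classifier_hidden_dim=8)
    vocab = make_vocab([fox_utterance.tokens])
    return SRPModel(config, vocab)


class TestElements:
    def test_avp_element_sequence(self, fox_utterance):
        els = elements_of(fox_utterance)
        assert [e.kind for e in els] == ["arg", "verb", "arg"]
        assert els[0].tokens == ("the", "fox")
        assert els[2].tokens == ("the", "chicken")

    def test_plain_tokens_are_single_elements(self):
        utt = make_utterance(tokens=("well", "the", "fox", "hunts", "now"), verb=(3, 4),
                             args=(((1, 3), "A", "OTHER"),))
        els = elements_of(utt)
        assert [e.kind for e in els] == ["plain", "arg", "verb", "plain"]


class TestEmbedding:
    def test_embed_element_deterministic(self, small_model):
        v1 = small_model.embed_element(["the", "fox"])
        v2 = small_model.embed_element(["the", "fox"])
        assert np.array_equal(v1, v2)

    def test_order_sensitivity(self, small_model):
        v1 = small_model.embed_element(["the", "fox"])
        v2 = small_model.embed_element(["fox", "the"])
        assert not np.allclose(v1, v2)

    def test_hash_embedding_stable_for_unknown_words(self, small_model):
        v1 = small_model._token_vector("zzyzx")
        # fresh model, same seed: identical vector (process-independent hashing)
        other = SRPModel(small_model.config, small_model.vocab)
        assert np.array_equal(v1, other._token_vector("zzyzx"))

    def test_empty_element_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.embed_element([])

    def test_char_conv_mode_runs(self, fox_utterance):
        config = ModelConfig(seed=5, embedding_mode="char_conv", embedding_dim=8,
                             encoder_hidden_dim=8, processor_hidden_dim=10,
                             classifier_hidden_dim=8)
        model = SRPModel(config, make_vocab([fox_utterance.tokens]))
        traj = incremental_forward(fox_utterance, model)
        traj.validate()

    def test_pretrained_vectors_mode(self, tmp_path, fox_utterance):
        words = sorted(set(fox_utterance.tokens))
        rng = np.random.default_rng(0)
        lines = [f"{w} " + " ".join(f"{x:.4f}" for x in rng.standard_normal(8)) for w in words]
        vec_path = tmp_path / "vecs.txt"
        vec_path.write_text("\n".join(lines) + "\n")
        config = ModelConfig(seed=5, embedding_mode="pretrained_vectors", embedding_dim=8,
                             encoder_hidden_dim=8, processor_hidden_dim=10,
                             classifier_hidden_dim=8, vectors_path=str(vec_path))
        model = SRPModel(config, make_vocab([fox_utterance.tokens]))
        traj = incremental_forward(fox_utterance, model)
        traj.validate()


class TestIncrementalForward:
    def test_untrained_model_gives_exact_uniform(self, small_model, fox_utterance):
        traj = incremental_forward(fox_utterance, small_model)
        for point in traj.points:
            for pa, pp in point.values():
                assert pa == 0.5 and pp == 0.5

    def test_avp_trajectory_structure(self, small_model, fox_utterance):
        traj = incremental_forward(fox_utterance, small_model)
        assert traj.n_points == 3
        assert len(traj.points[0]) == 1          # only A seen
        assert len(traj.points[1]) == 1
        assert len(traj.points[2]) == 2          # both arguments
        counts = {r: sum(r in p for p in traj.points) for r in ("A", "P")}
        assert counts == {"A": 3, "P": 1}
        traj.validate()

    def test_normalization_on_trained_model(self, trained_det_model):
        model, held_out = trained_det_model
        for u in held_out[:40]:
            traj = incremental_forward(u, model)
            traj.validate(tol=1e-6)

    def test_next_word_distributions(self, small_model, fox_utterance):
        traj = incremental_forward(fox_utterance, small_model, include_next_word=True)
        assert len(traj.next_word) == traj.n_points
        for dist in traj.next_word:
            assert dist.shape == (len(small_model.vocab),)
            assert dist.sum() == pytest.approx(1.0)


class TestTrainingLoss:
    def test_uniform_role_prediction_is_ln2(self, small_model):
        utt = make_utterance(tokens=("go", "home"), verb=(0, 1), verb_class="motion",
                             args=(((1, 2), "P", "OTHER"),))
        config_no_nw = ModelConfig(**{**small_model.config.__dict__, "loss_mix": 0.0})
        model = SRPModel(config_no_nw, small_model.vocab)
        loss = training_loss([utt], model, "main")
        assert loss == pytest.approx(math.log(2), abs=1e-9)

    def test_two_argument_loss_is_2ln2(self, small_model, fox_utterance):
        config_no_nw = ModelConfig(**{**small_model.config.__dict__, "loss_mix": 0.0})
        model = SRPModel(config_no_nw, make_vocab([fox_utterance.tokens]))
        loss = training_loss([fox_utterance], model, "main")
        assert loss == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_pretrain_loss_uniform_is_log_vocab(self, small_model):
        # zero-initialized next-word output layer -> uniform over vocab
        seqs = [["the", "fox"], ["fox", "the", "fox"]]
        loss = training_loss(seqs, small_model, "pretrain")
        assert loss == pytest.approx(math.log(len(small_model.vocab)), abs=1e-9)

    def test_hand_built_batch_oracle(self, fox_utterance):
        # independent scalar computation of the joint loss for one utterance
        config = ModelConfig(seed=7, embedding_dim=6, encoder_hidden_dim=6,
                             processor_hidden_dim=6, classifier_hidden_dim=6, loss_mix=0.5)
        vocab = make_vocab([fox_utterance.tokens])
        model = SRPModel(config, vocab)
        rng = np.random.default_rng(0)
        for name, t in model.store.items():  # randomize outputs away from zero
            t.data = rng.standard_normal(t.data.shape) * 0.3
        traj = incremental_forward(fox_utterance, model, include_next_word=True)
        role_ce = -sum(
            math.log(traj.points[-1][role][0 if role == "A" else 1])
            for role in ("A", "P")
        )
        els = elements_of(fox_utterance)
        targets = [vocab[els[1].tokens[0]], vocab[els[2].tokens[0]], vocab[EOS]]
        nw_ce = -np.mean([math.log(traj.next_word[t][targets[t]]) for t in range(3)])
        expected = role_ce + 0.5 * nw_ce
        got = training_loss([fox_utterance], model, "main")
        assert got == pytest.approx(expected, rel=1e-9)

    def test_main_stage_requires_annotations(self, small_model):
        with pytest.raises(ValueError):
            training_loss([["just", "tokens"]], small_model, "main")
        with pytest.raises(ValueError):
            training_loss([], small_model, "main")


class TestTraining:
    def test_pretrain_determinism_and_frozen_classifier(self):
        spec = load_preset("deterministic_cue")
        adu = generate_adu_text(spec, 1500, seed=3)
        config = ModelConfig(seed=3, max_epochs=2)
        m1 = pretrain(adu, config)
        m2 = pretrain(adu, config)
        s1, s2 = m1.store.state_dict(), m2.store.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)
        fresh = SRPModel(config, m1.vocab)
        for k in s1:
            if k.startswith("role_clf"):
                assert np.array_equal(s1[k], fresh.store.state_dict()[k])

    def test_pretraining_reduces_perplexity(self):
        spec = load_preset("deterministic_cue")
        adu = generate_adu_text(spec, 4000, seed=4)
        held_out, train = adu[:40], adu[40:]
        config = ModelConfig(seed=4, max_epochs=4)
        model0 = SRPModel(config, make_vocab(train))
        loss0 = training_loss(held_out, model0, "pretrain")
        log = []
        fitted = pretrain(train, config, vocab=model0.vocab, log=log)
        loss1 = training_loss(held_out, fitted, "pretrain")
        assert loss1 < loss0
        assert all(e["stage"] == "pretrain" for e in log)

    def test_pretrain_negative_control_disjoint_lexicon(self):
        spec_x = load_preset("deterministic_cue")
        spec_y = load_preset("agent_preference")  # different seeds/lexicons below
        adu_x = generate_adu_text(spec_x, 3000, seed=5)
        adu_y = generate_adu_text(spec_y, 800, seed=99)
        config = ModelConfig(seed=5, max_epochs=3)
        fitted = pretrain(adu_x, config)
        loss_y = training_loss(adu_y, fitted, "pretrain")
        uniform = math.log(len(fitted.vocab))
        # no transfer to a disjoint lexicon: never beats the uniform baseline
        # (typically worse, since every out-of-lexicon target maps to UNK)
        assert loss_y >= uniform - 0.05
        loss_x = training_loss(adu_x[:40], fitted, "pretrain")
        assert loss_x < uniform  # sanity: in-lexicon text is predicted above uniform

    def test_train_main_determinism(self, det_corpus):
        utts = list(det_corpus)[:200]
        config = ModelConfig(seed=6, max_epochs=2)
        vocab = make_vocab([u.tokens for u in utts])

        def run():
            base = SRPModel(config, vocab)
            return train_main(base, utts[:160], utts[160:], config, from_scratch=True)

        s1, s2 = run().store.state_dict(), run().store.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_loss_components_logged(self, det_corpus):
        utts = list(det_corpus)[:120]
        config = ModelConfig(seed=6, max_epochs=1)
        base = SRPModel(config, make_vocab([u.tokens for u in utts]))
        log = []
        train_main(base, utts[:100], utts[100:], config, from_scratch=True, log=log)
        assert "train_role_loss" in log[0] and "train_next_word_loss" in log[0]

    def test_label_shuffled_control_near_baseline(self, det_corpus, rng):
        from rolepred.corpus import ArgumentSpan, Role

        utts = []
        for u in list(det_corpus)[:400]:
            if len(u.arguments) != 2:
                continue
            args = list(u.arguments)
            if rng.random() < 0.5:  # shuffle the role labels, keep everything else
                args = [ArgumentSpan(a.start, a.end, Role("A" if a.role == Role.P else "P"),
                                     a.nominality) for a in args]
            utts.append(type(u)(id=u.id, language=u.language, tokens=list(u.tokens),
                                verb_span=u.verb_span, verb_class=u.verb_class, arguments=args))
        n = len(utts)
        n_train, n_val = int(0.7 * n), int(0.15 * n)
        config = ModelConfig(seed=8, max_epochs=3)
        base = SRPModel(config, make_vocab([u.tokens for u in utts]))
        fitted = train_main(base, utts[:n_train], utts[n_train: n_train + n_val],
                            config, from_scratch=True)
        test = utts[n_train + n_val:]
        acc = evaluate_role_accuracy(fitted, test)
        n_args = 2 * len(test)
        se = math.sqrt(0.25 / n_args)
        assert abs(acc - 0.5) < 3 * se

    def test_learnability_deterministic_cue(self, trained_det_model):
        model, held_out = trained_det_model
        assert evaluate_role_accuracy(model, held_out) >= 0.95

    def test_empty_training_set_rejected(self, small_model):
        with pytest.raises(ValueError):
            train_main(small_model, [], [], small_model.config)

    def test_pretrain_empty_rejected(self):
        with pytest.raises(ValueError):
            pretrain([], ModelConfig())


class TestSerialization:
    def test_save_load_bit_identical_trajectories(self, trained_det_model, tmp_path):
        model, held_out = trained_det_model
        path = tmp_path / "model.npz"
        model.save(path)
        again = SRPModel.load(path)
        for u in held_out[:10]:
            t1 = incremental_forward(u, model)
            t2 = incremental_forward(u, again)
            assert t1.points == t2.points


@pytest.fixture(scope="module")
def cv_result(det_corpus):
    corpus = Corpus(utterances=list(det_corpus)[:100], metadata={})
    config = ModelConfig(seed=9, max_epochs=2)
    return corpus, kfold_evaluate(corpus, 10, config)


class TestKFold:
    def test_partition_exactness(self, cv_result):
        corpus, result = cv_result
        folds = {}
        for uid, f in result.assignments.items():
            folds.setdefault(f, set()).add(uid)
        assert len(folds) == 10
        assert all(len(s) == 10 for s in folds.values())
        union = set.union(*folds.values())
        assert union == {u.id for u in corpus}

    def test_every_utterance_has_trajectory(self, cv_result):
        corpus, result = cv_result
        assert set(result.trajectories) == {u.id for u in corpus}

    def test_fold_assignment_deterministic(self, det_corpus):
        corpus = Corpus(utterances=list(det_corpus)[:60], metadata={})
        config = ModelConfig(seed=10, max_epochs=1)
        r1 = kfold_evaluate(corpus, 5, config)
        r2 = kfold_evaluate(corpus, 5, config)
        assert r1.assignments == r2.assignments
        assert r1.fold_table.equals(r2.fold_table)

    def test_corpus_smaller_than_k_rejected(self, det_corpus):
        corpus = Corpus(utterances=list(det_corpus)[:5], metadata={})
        with pytest.raises(ValueError, match="smaller than k"):
            kfold_evaluate(corpus, 10, ModelConfig())


class TestMonotoneInformation:
    def test_p_correct_rises_after_disambiguating_cue(self, trained_det_model):
        """On the deterministic-cue preset the case marker arrives with the
        argument itself, so P(correct) from the argument onward must beat the
        pre-verb-only baseline on average."""
        model, held_out = trained_det_model
        before, after = [], []
        for u in held_out:
            traj = incremental_forward(u, model)
            for role, ta in traj.arg_elements.items():
                idx = 0 if role == "A" else 1
                before.append(traj.points[ta][role][idx])
                after.append(traj.points[-1][role][idx])
        assert np.mean(after) >= np.mean(before) - 0.02
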
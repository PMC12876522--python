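"""ProtoNet-ML and BatchBased: closed-form oracles and training contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gfchest as g
from gfchest.autodiff import sigmoid
from gfchest.backbone import MLPBackbone, EncodingConfig
from gfchest.batchbased import AdaptConfig, LinearHead, subset_size
from gfchest.protonet import _distances, compute_prototypes, protonet_ml_predict

RNG = np.random.default_rng(7)


class TestComputePrototypes:
    def test_single_positive_is_that_embedding(self):
        emb = RNG.normal(size=(3, 4))
        labels = np.array([[1, 0], [0, 1], [0, 0]])
        protos = compute_prototypes(emb, labels, ("a", "b"))
        np.testing.assert_allclose(protos.prototypes[0], emb[0])
        np.testing.assert_allclose(protos.prototypes[1], emb[1])

    def test_symmetric_positives_average_to_zero(self):
        e = RNG.normal(size=4)
        emb = np.stack([e, -e])
        labels = np.array([[1], [1]])
        protos = compute_prototypes(emb, labels, ("a",))
        np.testing.assert_allclose(protos.prototypes[0], np.zeros(4), atol=1e-12)

    def test_mu_matches_brute_force_loop(self):
        emb = RNG.normal(size=(10, 5))
        labels = (RNG.random((10, 3)) < 0.5).astype(int)
        labels[0] = 1  # every class inhabited
        protos = compute_prototypes(emb, labels, ("a", "b", "c"))
        for c in range(3):
            z = emb[labels[:, c] == 1].mean(axis=0)
            mu = np.mean([np.linalg.norm(e - z) for e in emb])
            assert protos.mu[c] == pytest.approx(mu)

    def test_duplicated_records_equal_weighted_mean(self):
        emb = RNG.normal(size=(4, 3))
        labels = np.array([[1], [1], [0], [0]])
        dup = np.concatenate([emb, emb[:1]])
        dup_labels = np.concatenate([labels, [[1]]])
        protos = compute_prototypes(dup, dup_labels, ("a",))
        weighted = (2 * emb[0] + emb[1]) / 3
        np.testing.assert_allclose(protos.prototypes[0], weighted)

    def test_zero_positive_class_rejected(self):
        emb = RNG.normal(size=(3, 2))
        labels = np.array([[1, 0], [1, 0], [0, 0]])
        with pytest.raises(ValueError, match="b"):
            compute_prototypes(emb, labels, ("a", "b"))


class TestProtoNetMLPredict:
    def test_identical_embeddings_give_half(self):
        emb = np.ones((4, 3))
        labels = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        protos = compute_prototypes(emb, labels, ("a", "b"))
        probs = protonet_ml_predict(np.ones((2, 3)), protos)
        np.testing.assert_allclose(probs, 0.5)

    def test_point_at_mean_distance_scores_half(self):
        emb = RNG.normal(size=(6, 2))
        labels = np.ones((6, 1), dtype=int)
        protos = compute_prototypes(emb, labels, ("a",))
        direction = np.array([1.0, 0.0])
        test_point = protos.prototypes[0] + protos.mu[0] * direction
        probs = protonet_ml_predict(test_point[None, :], protos)
        assert probs[0, 0] == pytest.approx(0.5)

    def test_one_dimensional_closed_form(self):
        """Prototypes at 0 and 10 with mu=(5,5): a point at 1 scores
        (sigmoid(4), sigmoid(-4))."""
        protos = g.PrototypeSet(
            classes=("a", "b"),
            prototypes=np.array([[0.0], [10.0]]),
            mu=np.array([5.0, 5.0]),
        )
        probs = protonet_ml_predict(np.array([[1.0]]), protos)
        np.testing.assert_allclose(
            probs[0], [sigmoid(np.array(4.0)), sigmoid(np.array(-4.0))]
        )

    def test_threshold_rule(self):
        """p > 0.5 exactly when the distance is below the class mean."""
        emb = RNG.normal(size=(8, 3))
        labels = (RNG.random((8, 2)) < 0.6).astype(int)
        labels[0] = 1
        protos = compute_prototypes(emb, labels, ("a", "b"))
        tst = RNG.normal(size=(10, 3))
        probs = protonet_ml_predict(tst, protos)
        d = np.sqrt(((tst[:, None] - protos.prototypes[None]) ** 2).sum(-1))
        np.testing.assert_array_equal(probs > 0.5, d < protos.mu[None, :])

    def test_translation_invariance(self):
        emb = RNG.normal(size=(6, 4))
        labels = (RNG.random((6, 2)) < 0.5).astype(int)
        labels[0] = 1
        tst = RNG.normal(size=(3, 4))
        shift = RNG.normal(size=4)
        base = protonet_ml_predict(tst, compute_prototypes(emb, labels, ("a", "b")))
        moved = protonet_ml_predict(
            tst + shift, compute_prototypes(emb + shift, labels, ("a", "b"))
        )
        np.testing.assert_allclose(base, moved, atol=1e-12)

    def test_dimension_mismatch(self):
        protos = g.PrototypeSet(("a",), np.zeros((1, 3)), np.zeros(1))
        with pytest.raises(ValueError, match="dim"):
            protonet_ml_predict(np.zeros((2, 4)), protos)

    def test_nearest_mean_ranking_agreement(self):
        """Single-class probabilities rank test points exactly opposite to
        their distance from the class mean (nearest-mean oracle)."""
        emb = np.concatenate([RNG.normal(1, 1, (5, 2)), RNG.normal(-1, 1, (5, 2))])
        labels = np.array([[1]] * 5 + [[0]] * 5)
        protos = compute_prototypes(emb, labels, ("a",))
        tst = RNG.normal(size=(20, 2))
        probs = protonet_ml_predict(tst, protos)[:, 0]
        dists = np.linalg.norm(tst - emb[:5].mean(0), axis=1)
        assert list(np.argsort(probs)) == list(np.argsort(dists)[::-1])

    @pytest.mark.parametrize("kind,p", [("minkowski", 1.0), ("minkowski", 3.0),
                                        ("cosine", 2.0)])
    def test_alternative_distances(self, kind, p):
        a = RNG.normal(size=(4, 3))
        b = RNG.normal(size=(2, 3))
        d = _distances(a, b, kind, p)
        if kind == "minkowski":
            expected = np.array(
                [[np.sum(np.abs(x - y) ** p) ** (1 / p) for y in b] for x in a]
            )
        else:
            expected = np.array(
                [[1 - x @ y / (np.linalg.norm(x) * np.linalg.norm(y)) for y in b]
                 for x in a]
            )
        np.testing.assert_allclose(d, expected)


class TestBatchBasedPredict:
    def test_zero_head_gives_half(self):
        head = LinearHead(
            W=g.autodiff.Tensor(np.zeros((4, 3))),
            b=g.autodiff.Tensor(np.zeros(3)),
            classes=("a", "b", "c"),
        )
        probs = g.batchbased_predict(RNG.normal(size=(5, 4)), head)
        np.testing.assert_allclose(probs, 0.5)

    def test_row_selector_head(self):
        head = LinearHead(
            W=g.autodiff.Tensor(np.eye(3)),
            b=g.autodiff.Tensor(np.zeros(3)),
            classes=("a", "b", "c"),
        )
        probs = g.batchbased_predict(np.eye(3)[:1], head)
        np.testing.assert_allclose(
            probs[0], [sigmoid(np.array(1.0)), 0.5, 0.5]
        )

    def test_matches_matrix_product_oracle(self):
        W = RNG.normal(size=(6, 4))
        b = RNG.normal(size=4)
        emb = RNG.normal(size=(9, 6))
        head = LinearHead(W=g.autodiff.Tensor(W), b=g.autodiff.Tensor(b),
                          classes=("a", "b", "c", "d"))
        np.testing.assert_allclose(
            g.batchbased_predict(emb, head), 1 / (1 + np.exp(-(emb @ W + b)))
        )

    def test_arity_mismatch(self):
        head = LinearHead(W=g.autodiff.Tensor(np.zeros((3, 2))),
                          b=g.autodiff.Tensor(np.zeros(2)), classes=("a", "b"))
        with pytest.raises(ValueError):
            g.batchbased_predict(np.zeros((1, 4)), head)


class TestSubsetSize:
    @pytest.mark.parametrize("n,ptc,expected", [
        (93, 0.5, 47),   # 46.5 rounds half away from zero
        (100, 0.5, 50),
        (10, 0.25, 3),   # 2.5 -> 3
        (1, 0.01, 1),    # floor of 1
        (4, 1.0, 4),
    ])
    def test_rounding(self, n, ptc, expected):
        assert subset_size(n, ptc) == expected

    def test_adapt_config_validation(self):
        with pytest.raises(ValueError):
            AdaptConfig(t_steps=-1)
        with pytest.raises(ValueError):
            AdaptConfig(ptc_trn=0.0)
        with pytest.raises(ValueError):
            AdaptConfig(ptc_trn=1.5)


class TestAdaptation:
    def test_backbone_frozen_during_adaptation(self, batchbased_easy, easy_setup):
        _, table, part, split, renderer = easy_setup
        episode = g.generate_episode(
            table, split, part, g.EpisodeSpec(2, 1, 5, 5),
            np.random.default_rng(3), pool="tst",
        )
        before = batchbased_easy.backbone_.checksum()
        batchbased_easy.adapt(episode, table, renderer,
                              rng=np.random.default_rng(0))
        assert batchbased_easy.backbone_.checksum() == before

    def test_zero_steps_returns_fresh_head_predictions(self, batchbased_easy,
                                                       easy_setup):
        _, table, part, split, renderer = easy_setup
        episode = g.generate_episode(
            table, split, part, g.EpisodeSpec(2, 1, 5, 5),
            np.random.default_rng(3), pool="tst",
        )
        pred = batchbased_easy.adapt(
            episode, table, renderer, config=AdaptConfig(t_steps=0),
            rng=np.random.default_rng(0),
        )
        # Small random head, zero bias: probabilities hover near chance.
        assert np.abs(pred.probs - 0.5).max() < 0.05

    def test_adaptation_is_seed_deterministic(self, batchbased_easy, easy_setup):
        _, table, part, split, renderer = easy_setup
        episode = g.generate_episode(
            table, split, part, g.EpisodeSpec(2, 1, 5, 5),
            np.random.default_rng(3), pool="tst",
        )
        a = batchbased_easy.adapt(episode, table, renderer,
                                  rng=np.random.default_rng(5))
        b = batchbased_easy.adapt(episode, table, renderer,
                                  rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_separable_episode_reaches_high_auc(self, batchbased_easy, easy_setup):
        _, table, part, split, renderer = easy_setup
        rng = np.random.default_rng(13)
        scores = []
        for _ in range(5):
            episode = g.generate_episode(
                table, split, part, g.EpisodeSpec(2, 1, 30, 30), rng, pool="tst"
            )
            pred = batchbased_easy.adapt(episode, table, renderer, rng=rng)
            labels = episode.label_matrix(table, "tst")
            scores.append(g.pooled_auc(labels, pred.probs))
        assert np.mean(scores) >= 95.0


class TestTrainingContracts:
    def test_protonet_zero_lr_leaves_parameters_unchanged(self, easy_setup):
        _, table, part, split, renderer = easy_setup
        model = g.ProtoNetML(
            lr=0.0, episodes_per_epoch=3, max_epochs=1, val_episodes=2,
            train_spec=g.EpisodeSpec(3, 0, 2, 2),
            val_spec=g.EpisodeSpec(2, 1, 2, 2), random_state=4,
        )
        model.fit(table, split, part, renderer)
        reference = MLPBackbone(
            input_size=model.input_size, patch_size=model.patch_size,
            hidden_dim=model.hidden_dim, feature_dim=model.feature_dim,
            encoding=EncodingConfig(model.encoding_kind, model.encoding_size),
            seed=int(np.random.SeedSequence(entropy=4, spawn_key=(0,))
                     .generate_state(1)[0] % 2**31),
        )
        assert model.backbone_.checksum() == reference.checksum()

    def test_protonet_loss_trajectory_reproducible(self, easy_setup):
        _, table, part, split, renderer = easy_setup
        kwargs = dict(
            episodes_per_epoch=5, max_epochs=2, patience=5, val_episodes=2,
            train_spec=g.EpisodeSpec(3, 0, 3, 3),
            val_spec=g.EpisodeSpec(2, 1, 2, 2), random_state=9,
        )
        a = g.ProtoNetML(**kwargs).fit(table, split, part, renderer)
        b = g.ProtoNetML(**kwargs).fit(table, split, part, renderer)
        assert a.history_["loss"].tolist() == b.history_["loss"].tolist()

    def test_batchbased_zero_epochs_returns_initialization(self, easy_setup):
        _, table, part, split, renderer = easy_setup
        model = g.BatchBased(max_epochs=0, random_state=4)
        model.fit(table, split, part, renderer)
        reference = MLPBackbone(
            input_size=model.input_size, patch_size=model.patch_size,
            hidden_dim=model.hidden_dim, feature_dim=model.feature_dim,
            encoding=EncodingConfig(model.encoding_kind, model.encoding_size),
            seed=int(np.random.SeedSequence(entropy=4, spawn_key=(0,))
                     .generate_state(1)[0] % 2**31),
        )
        assert model.backbone_.checksum() == reference.checksum()
        assert model.n_epochs_ == 0

    def test_batchbased_loss_decreases_on_separable_pool(self, easy_setup):
        _, table, part, split, renderer = easy_setup
        model = g.BatchBased(
            examples_per_epoch=600, max_epochs=4, patience=10, val_episodes=2,
            lr=3e-4, val_spec=g.EpisodeSpec(2, 1, 2, 2), random_state=2,
        )
        model.fit(table, split, part, renderer)
        losses = model.history_["loss"].tolist()
        assert losses == sorted(losses, reverse=True)

    def test_early_stopping_honours_patience(self, easy_setup):
        _, table, part, split, renderer = easy_setup
        model = g.BatchBased(
            examples_per_epoch=64, max_epochs=40, patience=2, val_episodes=2,
            lr=0.0, val_spec=g.EpisodeSpec(2, 1, 2, 2), random_state=2,
        )
        model.fit(table, split, part, renderer)
        best_epoch = int(model.history_["val_hm"].idxmax())
        assert model.n_epochs_ <= best_epoch + model.patience + 1

    def test_sklearn_param_interface(self):
        model = g.ProtoNetML(lr=0.5)
        assert model.get_params()["lr"] == 0.5
        model.set_params(encoding_size=64)
        assert model.encoding_size == 64
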
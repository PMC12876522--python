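"""ProtoNet-ML: prototypical networks extended to multi-label episodes.

For each episode class ``c`` the method computes a prototype ``z_c`` — the
mean embedding of the training examples labeled ``c`` — and the mean distance
``mu_c`` between ``z_c`` and *all* training embeddings in the episode
(positives of other classes and not-finding negatives included).  A test
example's probability for class ``c`` is

    p(y[c] = 1 | x) = sigmoid(mu_c - d(f(x), z_c))

so examples closer to the prototype than the episode's average score above
0.5, independently per class: one example may exceed the threshold for several
prototypes at once, which is what makes the rule multi-label.

Episodic pre-training minimises the binary cross-entropy of these
probabilities on each episode's test subset and backpropagates into the
backbone and encoding parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .autodiff import AdamW, Tensor, sigmoid
from .backbone import EncodingConfig, MLPBackbone
from .data_model import MetadataTable
from .episodes import Episode, EpisodeSpec, generate_episode
from .evaluation import PredictionMatrix, aggregate, score_episode


@dataclass(frozen=True)
class PrototypeSet:
    """Per-class prototypes and mean training distances for one episode."""

    classes: tuple[str, ...]
    prototypes: np.ndarray  # (n_way, D)
    mu: np.ndarray          # (n_way,), non-negative
    distance: str = "euclidean"
    minkowski_p: float = 2.0

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.prototypes) or len(self.classes) != len(
            self.mu
        ):
            raise ValueError("one (prototype, mu) pair required per class")
        if np.any(self.mu < 0):
            raise ValueError("mean distances must be non-negative")


def _distances(
    points: np.ndarray, centers: np.ndarray, kind: str, p: float
) -> np.ndarray:
    diff = points[:, None, :] - centers[None, :, :]
    if kind == "euclidean":
        return np.sqrt((diff**2).sum(-1))
    if kind == "minkowski":
        return (np.abs(diff) ** p).sum(-1) ** (1.0 / p)
    if kind == "cosine":
        pn = points / np.maximum(np.linalg.norm(points, axis=1, keepdims=True), 1e-12)
        cn = centers / np.maximum(
            np.linalg.norm(centers, axis=1, keepdims=True), 1e-12
        )
        return 1.0 - pn @ cn.T
    raise ValueError(f"unknown distance {kind!r}")


def compute_prototypes(
    trn_embeddings: np.ndarray,
    trn_labels: np.ndarray,
    classes: tuple[str, ...],
    distance: str = "euclidean",
    minkowski_p: float = 2.0,
) -> PrototypeSet:
    """Per-class mean embeddings and mean distances over the training subset.

    ``trn_labels`` is the episode's restricted 0/1 matrix aligned to
    ``classes``.  Every class needs at least one positive; ``mu`` averages the
    prototype's distance to *every* training embedding.
    """
    labels = np.asarray(trn_labels, dtype=float)
    emb = np.asarray(trn_embeddings, dtype=float)
    counts = labels.sum(axis=0)
    empty = np.flatnonzero(counts == 0)
    if len(empty):
        raise ValueError(
            f"classes with zero training positives: "
            f"{[classes[i] for i in empty]}"
        )
    protos = (labels.T @ emb) / counts[:, None]
    dists = _distances(emb, protos, distance, minkowski_p)
    mu = dists.mean(axis=0)
    return PrototypeSet(
        classes=tuple(classes),
        prototypes=protos,
        mu=mu,
        distance=distance,
        minkowski_p=minkowski_p,
    )


def protonet_ml_predict(
    tst_embeddings: np.ndarray, prototypes: PrototypeSet
) -> np.ndarray:
    """Probabilities sigmoid(mu_c - d(e, z_c)) per (test example, class)."""
    emb = np.asarray(tst_embeddings, dtype=float)
    if emb.shape[1] != prototypes.prototypes.shape[1]:
        raise ValueError(
            f"embedding dim {emb.shape[1]} != prototype dim "
            f"{prototypes.prototypes.shape[1]}"
        )
    d = _distances(
        emb, prototypes.prototypes, prototypes.distance, prototypes.minkowski_p
    )
    return sigmoid(prototypes.mu[None, :] - d)


class ProtoNetML(BaseEstimator):
    """Episodically trained multi-label prototypical network.

    Scikit-learn style estimator; because the unit of training data is an
    episode stream sampled from a metadata table rather than an (X, y) pair,
    :meth:`fit` takes the table, example split, class partition, and an image
    provider (a callable ``record -> 2-D array``).

    Parameters mirror the published defaults: AdamW with learning rate 1e-4,
    average-pooling encoding to 128 dimensions, early stopping on the
    meta-validation harmonic mean with patience 10.  ``episodes_per_epoch``,
    ``val_episodes`` and the episode specs control the desk-scale training
    budget.  ``val_episodes=0`` disables meta-validation and early
    stopping (training runs all epochs).

    Fitted attributes: ``backbone_``, ``history_`` (per-epoch loss and
    validation scores), ``n_epochs_``.
    """

    def __init__(
        self,
        input_size: int = 64,
        patch_size: int = 4,
        hidden_dim: int = 512,
        feature_dim: int = 256,
        encoding_kind: str = "average-pooling",
        encoding_size: int = 128,
        init: str = "looks-linear",
        distance: str = "euclidean",
        minkowski_p: float = 2.0,
        lr: float = 1e-4,
        weight_decay: float = 0.01,
        episodes_per_epoch: int = 1000,
        max_epochs: int = 150,
        patience: int = 10,
        val_episodes: int = 100,
        train_spec: EpisodeSpec | None = None,
        val_spec: EpisodeSpec | None = None,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.patch_size = patch_size
        self.hidden_dim = hidden_dim
        self.feature_dim = feature_dim
        self.encoding_kind = encoding_kind
        self.encoding_size = encoding_size
        self.init = init
        self.distance = distance
        self.minkowski_p = minkowski_p
        self.lr = lr
        self.weight_decay = weight_decay
        self.episodes_per_epoch = episodes_per_epoch
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_episodes = val_episodes
        self.train_spec = train_spec
        self.val_spec = val_spec
        self.random_state = random_state

    # -- training ----------------------------------------------------------

    def _episode_loss(self, episode: Episode, table, provider) -> Tensor:
        trn_images = provider.batch(table, episode.trn_ids)
        tst_images = provider.batch(table, episode.tst_ids)
        y_trn = episode.label_matrix(table, "trn").astype(float)
        y_tst = episode.label_matrix(table, "tst").astype(float)

        e_trn = self.backbone_.forward(trn_images)
        counts = y_trn.sum(axis=0)
        if np.any(counts == 0):
            raise ValueError("episode class without training positives")
        averaging = (y_trn / counts[None, :]).T  # (C, n_trn), rows sum to 1
        protos = ad.matmul(Tensor(averaging), e_trn)
        mu = ad.mean_axis0(ad.cdist(e_trn, protos))
        e_tst = self.backbone_.forward(tst_images)
        logits = ad.sub(mu, ad.cdist(e_tst, protos))
        return ad.bce_with_logits(logits, y_tst)

    def fit(self, table: MetadataTable, split, partition, provider):
        """Episodic pre-training with meta-validation early stopping."""
        train_spec = self.train_spec or EpisodeSpec(3, 0, 30, 30)
        val_spec = self.val_spec or EpisodeSpec(2, 1, 30, 30)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.random_state, spawn_key=(1,))
        )
        self.backbone_ = MLPBackbone(
            input_size=self.input_size,
            patch_size=self.patch_size,
            hidden_dim=self.hidden_dim,
            feature_dim=self.feature_dim,
            encoding=EncodingConfig(self.encoding_kind, self.encoding_size),
            init=self.init,
            seed=int(
                np.random.SeedSequence(
                    entropy=self.random_state, spawn_key=(0,)
                ).generate_state(1)[0]
                % 2**31
            ),
        )
        optimizer = AdamW(
            self.backbone_.parameters(),
            lr=self.lr,
            weight_decay=self.weight_decay,
        )
        history = []
        best_hm = -np.inf
        best_params = None
        best_epoch = -1
        for epoch in range(self.max_epochs):
            losses = []
            for _ in range(self.episodes_per_epoch):
                episode = generate_episode(
                    table, split, partition, train_spec, rng, pool="trn"
                )
                loss = self._episode_loss(episode, table, provider)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite episodic loss at epoch {epoch}: {loss.data}"
                    )
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                losses.append(float(loss.data))
            val_hm = (
                self._validation_hm(
                    table, split, partition, provider, val_spec, rng
                )
                if self.val_episodes > 0
                else float("nan")
            )
            history.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "val_hm": val_hm}
            )
            if self.val_episodes <= 0:
                continue
            if val_hm > best_hm:
                best_hm = val_hm
                best_epoch = epoch
                best_params = [p.data.copy() for p in self.backbone_.parameters()]
            elif epoch - best_epoch >= self.patience:
                break
        if best_params is not None:
            for p, data in zip(self.backbone_.parameters(), best_params):
                p.data = data
        self.history_ = pd.DataFrame(history)
        self.n_epochs_ = len(history)
        self.best_val_hm_ = best_hm if np.isfinite(best_hm) else None
        return self

    def _validation_hm(
        self, table, split, partition, provider, val_spec, rng
    ) -> float:
        scores = []
        for _ in range(self.val_episodes):
            episode = generate_episode(
                table, split, partition, val_spec, rng, pool="val"
            )
            pred = self.predict_episode(episode, table, provider)
            scores.append(score_episode(episode, pred, table))
        return aggregate(scores).means["hm"]

    # -- inference ---------------------------------------------------------

    def predict_episode(
        self, episode: Episode, table, provider, rng=None
    ) -> PredictionMatrix:
        """Prototype-rule probabilities for the episode's test subset."""
        emb_trn = self.backbone_.embed(provider.batch(table, episode.trn_ids))
        protos = compute_prototypes(
            emb_trn,
            episode.label_matrix(table, "trn"),
            episode.classes,
            distance=self.distance,
            minkowski_p=self.minkowski_p,
        )
        emb_tst = self.backbone_.embed(provider.batch(table, episode.tst_ids))
        probs = protonet_ml_predict(emb_tst, protos)
        return PredictionMatrix(
            probs=probs, classes=episode.classes, record_ids=episode.tst_ids
        )
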
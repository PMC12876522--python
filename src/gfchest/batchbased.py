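"""BatchBased: batch pre-training with episodic head adaptation.

Pre-training is ordinary multi-label batch training over *all* meta-training
classes: a linear head on top of the backbone, sigmoid outputs, binary
cross-entropy, AdamW.  At evaluation time the backbone is frozen; for each
episode a fresh head with one logit per episode class is trained for
``t_steps`` small steps, each on a uniformly resampled subset ``M`` of the
episode's training examples with ``|M| = round(ptc_trn * |D_trn|)``, and the
adapted head scores the test subset.  Early stopping during pre-training is
driven by the episode-based meta-validation harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .autodiff import SGD, AdamW, Tensor, sigmoid
from .backbone import EncodingConfig, MLPBackbone
from .data_model import MetadataTable
from .episodes import Episode, EpisodeSpec, generate_episode
from .evaluation import PredictionMatrix, aggregate, score_episode


@dataclass(frozen=True)
class AdaptConfig:
    """Episode-adaptation knobs: steps, subset proportion, head learning rate."""

    t_steps: int = 100
    ptc_trn: float = 0.5
    lr_head: float = 0.05

    def __post_init__(self) -> None:
        if self.t_steps < 0:
            raise ValueError("t_steps must be >= 0")
        if not 0.0 < self.ptc_trn <= 1.0:
            raise ValueError("ptc_trn must lie in (0, 1]")


def subset_size(n_trn: int, ptc_trn: float) -> int:
    """|M| = round-half-away-from-zero of ptc_trn * n_trn, floored at 1."""
    return max(1, int(np.floor(ptc_trn * n_trn + 0.5)))


@dataclass
class LinearHead:
    """Single fully connected layer mapping embeddings to per-class logits."""

    W: Tensor  # (D, n_classes)
    b: Tensor  # (n_classes,)
    classes: tuple[str, ...]

    @classmethod
    def initialize(
        cls,
        dim: int,
        classes: tuple[str, ...],
        rng: np.random.Generator,
        scale: float = 0.01,
    ) -> "LinearHead":
        # Small uniform weights, zero bias: near-chance initial probabilities.
        W = Tensor(
            rng.uniform(-scale, scale, size=(dim, len(classes))),
            requires_grad=True,
        )
        b = Tensor(np.zeros(len(classes)), requires_grad=True)
        return cls(W=W, b=b, classes=classes)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def logits(self, embeddings: np.ndarray) -> np.ndarray:
        return embeddings @ self.W.data + self.b.data


def batchbased_predict(
    tst_embeddings: np.ndarray, head: LinearHead
) -> np.ndarray:
    """Probabilities sigmoid(head(e)) per (test example, class)."""
    emb = np.asarray(tst_embeddings, dtype=float)
    if emb.shape[1] != head.W.data.shape[0]:
        raise ValueError(
            f"embedding dim {emb.shape[1]} != head input dim {head.W.data.shape[0]}"
        )
    return sigmoid(head.logits(emb))


class BatchBased(BaseEstimator):
    """Transfer-learning baseline: batch pre-training, frozen-backbone adaptation.

    Scikit-learn style estimator; :meth:`fit` takes the metadata table, example
    split, class partition, and an image provider, pre-trains backbone + head
    over the meta-training classes in mini-batches, and early-stops on the
    meta-validation harmonic mean.  :meth:`adapt` (also exposed as
    :meth:`predict_episode`) never touches backbone parameters.

    ``examples_per_epoch`` caps the number of pool images visited per epoch
    (None = all), the knob used for desk-scale runs.  ``include_normals``
    controls whether not-finding images (all-zero targets) join the
    pre-training batches.  ``val_episodes=0`` disables meta-validation and early
    stopping (training runs all epochs).

    Fitted attributes: ``backbone_``, ``head_``, ``history_``, ``n_epochs_``.
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
        batch_size: int = 64,
        lr: float = 1e-4,
        weight_decay: float = 0.01,
        max_epochs: int = 150,
        patience: int = 10,
        examples_per_epoch: int | None = None,
        include_normals: bool = True,
        t_steps: int = 100,
        ptc_trn: float = 0.5,
        lr_head: float = 0.05,
        val_episodes: int = 100,
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
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.examples_per_epoch = examples_per_epoch
        self.include_normals = include_normals
        self.t_steps = t_steps
        self.ptc_trn = ptc_trn
        self.lr_head = lr_head
        self.val_episodes = val_episodes
        self.val_spec = val_spec
        self.random_state = random_state

    # -- pre-training ------------------------------------------------------

    def fit(self, table: MetadataTable, split, partition, provider):
        """Mini-batch pre-training over the meta-training pool."""
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
        self.head_ = LinearHead.initialize(
            self.backbone_.output_dim, tuple(partition.trn_classes), rng
        )
        pool_ids = sorted(
            split.pool("trn") if self.include_normals else split.labeled("trn")
        )
        if not pool_ids:
            raise ValueError("meta-training pool is empty")
        rows = table.rows_for_ids(pool_ids)
        cols = table.vocabulary.indices(partition.trn_classes)
        targets = table.label_matrix[np.ix_(rows, cols)].astype(float)
        ids = np.array(pool_ids, dtype=object)

        optimizer = AdamW(
            self.backbone_.parameters() + self.head_.parameters(),
            lr=self.lr,
            weight_decay=self.weight_decay,
        )
        val_spec = self.val_spec or EpisodeSpec(2, 1, 30, 30)
        history = []
        best_hm = -np.inf
        best_params = None
        best_epoch = -1
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(ids))
            if self.examples_per_epoch is not None:
                order = order[: self.examples_per_epoch]
            losses = []
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                images = provider.batch(table, ids[batch])
                emb = self.backbone_.forward(images)
                logits = ad.add(ad.matmul(emb, self.head_.W), self.head_.b)
                loss = ad.bce_with_logits(logits, targets[batch])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite batch loss at epoch {epoch}: {loss.data}"
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
                best_params = [
                    p.data.copy()
                    for p in self.backbone_.parameters() + self.head_.parameters()
                ]
            elif epoch - best_epoch >= self.patience:
                break
        if best_params is not None:
            for p, data in zip(
                self.backbone_.parameters() + self.head_.parameters(), best_params
            ):
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
            pred = self.adapt(episode, table, provider, rng=rng)
            scores.append(score_episode(episode, pred, table))
        return aggregate(scores).means["hm"]

    # -- episodic adaptation ----------------------------------------------

    def adapt(
        self,
        episode: Episode,
        table,
        provider,
        config: AdaptConfig | None = None,
        rng: np.random.Generator | None = None,
    ) -> PredictionMatrix:
        """Freeze the backbone, train a fresh episode head, score the test set.

        Backbone outputs are computed once and cached; only the new head is
        updated (plain SGD with ``lr_head``), so backbone parameters are
        bit-identical before and after.
        """
        if config is None:
            config = AdaptConfig(self.t_steps, self.ptc_trn, self.lr_head)
        if rng is None:
            rng = np.random.default_rng(self.random_state)
        n_trn = len(episode.trn_ids)
        if config.t_steps > 0 and n_trn == 0:
            raise ValueError("cannot adapt on an empty episode training subset")

        emb_trn = self.backbone_.embed(provider.batch(table, episode.trn_ids))
        y_trn = episode.label_matrix(table, "trn").astype(float)
        head = LinearHead.initialize(
            self.backbone_.output_dim, episode.classes, rng
        )
        optimizer = SGD(head.parameters(), lr=config.lr_head)
        m = subset_size(n_trn, config.ptc_trn)
        for _ in range(config.t_steps):
            idx = rng.choice(n_trn, size=m, replace=False)
            logits = ad.add(ad.matmul(Tensor(emb_trn[idx]), head.W), head.b)
            loss = ad.bce_with_logits(logits, y_trn[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()

        emb_tst = self.backbone_.embed(provider.batch(table, episode.tst_ids))
        probs = batchbased_predict(emb_tst, head)
        return PredictionMatrix(
            probs=probs, classes=episode.classes, record_ids=episode.tst_ids
        )

    def predict_episode(
        self, episode: Episode, table, provider, rng=None
    ) -> PredictionMatrix:
        """Alias for :meth:`adapt` (the common evaluation-harness surface)."""
        return self.adapt(episode, table, provider, rng=rng)
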
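"""Multi-label episode generation.

An episode is a small self-contained classification task: a handful of classes
(some *seen* during pre-training, some *unseen*), a training subset with at
least ``k_trn`` positives per class, and a test subset with at least ``k_tst``
positives per class.  Because images are multi-labeled, an episode must also
*exclude* every class outside its own class set — otherwise off-episode
pathologies would leak in as unmodelled positives — and it must guarantee a
negative example for every class so that ROC-based metrics are defined.

The sampler fills classes in ascending order of their global frequency: scarce
classes get first pick of the eligible records, and the positives they drag in
for more frequent classes (multi-label spillover) count toward those classes'
quotas, which keeps episodes small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from typing import Literal, Sequence

import numpy as np

from .data_model import MetadataTable
from .partition import ClassPartition, ExampleSplit


class InsufficientDataError(RuntimeError):
    """A pool cannot supply the examples an episode requires."""


@dataclass(frozen=True)
class EpisodeSpec:
    """Episode shape: seen/unseen class counts and per-class minimum shots."""

    n_seen: int
    n_unseen: int
    k_trn: int = 30
    k_tst: int = 30

    def __post_init__(self) -> None:
        if self.n_seen < 0 or self.n_unseen < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_seen + self.n_unseen < 2:
            raise ValueError("an episode needs at least 2 classes (n-way >= 2)")
        if self.k_trn < 1 or self.k_tst < 1:
            raise ValueError("k_trn and k_tst must be >= 1")

    @property
    def n_way(self) -> int:
        return self.n_seen + self.n_unseen


@dataclass(frozen=True)
class Episode:
    """A sampled episode: classes, excluded set, and train/test record ids.

    ``classes`` holds all episode classes in the sampling (ascending global
    frequency) order; prediction matrices align their columns to it.
    """

    seen_classes: tuple[str, ...]
    unseen_classes: tuple[str, ...]
    excluded_classes: frozenset[str]
    trn_ids: tuple[str, ...]
    tst_ids: tuple[str, ...]
    pool: str
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.classes:
            object.__setattr__(self, "classes", self.seen_classes + self.unseen_classes)

    @property
    def n_way(self) -> int:
        return len(self.classes)

    def seen_mask(self) -> np.ndarray:
        seen = set(self.seen_classes)
        return np.array([c in seen for c in self.classes])

    def label_matrix(self, table: MetadataTable, subset: str = "tst") -> np.ndarray:
        """0/1 matrix of the restricted label vectors over ``classes``."""
        ids = self.tst_ids if subset == "tst" else self.trn_ids
        rows = table.rows_for_ids(ids)
        cols = table.vocabulary.indices(self.classes)
        return table.label_matrix[np.ix_(rows, cols)].astype(np.int8)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seen_classes": list(self.seen_classes),
                "unseen_classes": list(self.unseen_classes),
                "excluded_classes": sorted(self.excluded_classes),
                "trn_ids": list(self.trn_ids),
                "tst_ids": list(self.tst_ids),
                "pool": self.pool,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Episode":
        data = json.loads(text)
        return cls(
            seen_classes=tuple(data["seen_classes"]),
            unseen_classes=tuple(data["unseen_classes"]),
            excluded_classes=frozenset(data["excluded_classes"]),
            trn_ids=tuple(data["trn_ids"]),
            tst_ids=tuple(data["tst_ids"]),
            pool=data["pool"],
        )


def count_missing(
    subset_ids: Sequence[str],
    table: MetadataTable,
    pathology: str,
    k: int,
) -> int:
    """Number of additional positives of ``pathology`` needed to reach ``k``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if not len(subset_ids):
        return k
    rows = table.rows_for_ids(subset_ids)
    col = table.vocabulary.index(pathology)
    present = int(table.label_matrix[rows, col].sum())
    return max(0, k - present)


def _sort_by_frequency(
    classes: Sequence[str], freqs: dict[str, int], vocab_rank: dict[str, int]
) -> list[str]:
    return sorted(classes, key=lambda c: (freqs[c], vocab_rank[c]))


def generate_episode(
    table: MetadataTable,
    split: ExampleSplit,
    partition: ClassPartition,
    spec: EpisodeSpec,
    rng: np.random.Generator,
    pool: Literal["trn", "val", "tst"] = "tst",
    unseen_source: Literal["val", "tst"] | None = None,
    frequency_scope: Literal["global", "pool"] = "global",
    negatives: Literal["per-class", "shared"] = "per-class",
) -> Episode:
    """Sample one episode from a pool.

    Seen classes are drawn uniformly without replacement from the
    meta-training classes, unseen classes from the meta-validation or meta-test
    classes (``unseen_source`` defaults to the pool itself, or ``"val"`` for
    the meta-training pool).  Both lists are sorted by ascending class
    frequency — globally in the full table by default, within the pool when
    ``frequency_scope="pool"``.  The training subset is filled class by class
    in ascending-frequency order from the eligible set (pool records carrying
    no excluded class): for each class the number of still-missing positives is
    sampled fresh, then a not-finding record is added (one per class iteration
    by default; a single shared negative per subset when
    ``negatives="shared"``).  The test subset is built the same way from the
    eligible records not already used for training.

    Raises :class:`InsufficientDataError` naming the class or resource when the
    pool cannot satisfy the spec.
    """
    vocab = table.vocabulary
    vocab_rank = {name: i for i, name in enumerate(vocab.names)}

    if unseen_source is None:
        unseen_source = "val" if pool == "trn" else pool
    if spec.n_seen > len(partition.trn_classes):
        raise InsufficientDataError(
            f"n_seen={spec.n_seen} exceeds the {len(partition.trn_classes)} "
            "meta-training classes"
        )
    unseen_pool_classes = partition.classes_for(unseen_source)
    if spec.n_unseen > len(unseen_pool_classes):
        raise InsufficientDataError(
            f"n_unseen={spec.n_unseen} exceeds the {len(unseen_pool_classes)} "
            f"{unseen_source} classes"
        )

    seen = tuple(
        rng.choice(np.array(partition.trn_classes, dtype=object),
                   size=spec.n_seen, replace=False)
    ) if spec.n_seen else ()
    unseen = tuple(
        rng.choice(np.array(unseen_pool_classes, dtype=object),
                   size=spec.n_unseen, replace=False)
    ) if spec.n_unseen else ()

    pool_rows = table.rows_for_ids(sorted(split.pool(pool)))
    pool_mask = np.zeros(len(table), dtype=bool)
    pool_mask[pool_rows] = True

    if frequency_scope == "global":
        counts = table.class_counts()
    else:
        counts = table.label_matrix[pool_mask].sum(axis=0).astype(int)
    freqs = dict(zip(vocab.names, counts.tolist()))

    seen = tuple(_sort_by_frequency(seen, freqs, vocab_rank))
    unseen = tuple(_sort_by_frequency(unseen, freqs, vocab_rank))
    episode_classes = set(seen) | set(unseen)
    excluded = frozenset(vocab.names) - episode_classes
    fill_order = _sort_by_frequency(list(episode_classes), freqs, vocab_rank)

    matrix = table.label_matrix
    excluded_cols = vocab.indices(excluded) if excluded else np.array([], dtype=int)
    clean = (
        ~matrix[:, excluded_cols].any(axis=1)
        if len(excluded_cols)
        else np.ones(len(table), dtype=bool)
    )
    eligible = pool_mask & clean
    normal_mask = table.not_finding

    def build_subset(k: int, blocked: np.ndarray) -> np.ndarray:
        selected = np.zeros(len(table), dtype=bool)
        for pathology in fill_order:
            col = vocab.index(pathology)
            have = int((selected & matrix[:, col]).sum())
            missing = max(0, k - have)
            if missing:
                candidates = np.flatnonzero(
                    eligible & ~blocked & ~selected & matrix[:, col]
                )
                if len(candidates) < missing:
                    raise InsufficientDataError(
                        f"pool {pool!r}: class {pathology!r} has "
                        f"{len(candidates)} eligible positives, {missing} needed"
                    )
                take = rng.choice(candidates, size=missing, replace=False)
                selected[take] = True
            if negatives == "per-class":
                nf = np.flatnonzero(eligible & ~blocked & ~selected & normal_mask)
                if not len(nf):
                    raise InsufficientDataError(
                        f"pool {pool!r}: no not-finding record available"
                    )
                selected[rng.choice(nf)] = True
        if negatives == "shared" or not (selected & normal_mask).any():
            nf = np.flatnonzero(eligible & ~blocked & ~selected & normal_mask)
            if not len(nf):
                raise InsufficientDataError(
                    f"pool {pool!r}: no not-finding record available"
                )
            selected[rng.choice(nf)] = True
        return selected

    trn_selected = build_subset(spec.k_trn, blocked=np.zeros(len(table), dtype=bool))
    tst_selected = build_subset(spec.k_tst, blocked=trn_selected)

    return Episode(
        seen_classes=seen,
        unseen_classes=unseen,
        excluded_classes=excluded,
        trn_ids=tuple(table.ids[np.flatnonzero(trn_selected)]),
        tst_ids=tuple(table.ids[np.flatnonzero(tst_selected)]),
        pool=pool,
    )


def generate_episodes(
    table: MetadataTable,
    split: ExampleSplit,
    partition: ClassPartition,
    spec: EpisodeSpec,
    count: int,
    seed: int,
    **kwargs,
) -> list[Episode]:
    """Generate ``count`` episodes from one seeded generator."""
    rng = np.random.default_rng(seed)
    return [
        generate_episode(table, split, partition, spec, rng, **kwargs)
        for _ in range(count)
    ]
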
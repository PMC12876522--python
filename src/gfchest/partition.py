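"""Class-level meta-partition and disjoint example pools.

Classes are split into meta-training / meta-validation / meta-test sets by the
count-based rule of the combined corpus: the meta-test set takes the scarcest
classes that appear in *all* sources (so that every evaluation class is
represented across hospitals), meta-training takes the most frequent of the
remainder, and meta-validation the rest.  Examples are then divided into three
disjoint pools so that no image is shared between meta-training,
meta-validation, and meta-test episodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MetadataTable
from .reference import REFERENCE_NORMALS

#: Default not-finding allocation, the published per-meta-set normal counts
#: normalised (99,983 : 1,788 : 54,969).
DEFAULT_NORMAL_FRACTIONS: tuple[float, float, float] = tuple(
    v / sum(REFERENCE_NORMALS.values()) for v in REFERENCE_NORMALS.values()
)

POOLS = ("trn", "val", "tst")


class PartitionError(ValueError):
    """Raised when a valid class partition cannot be built."""


@dataclass(frozen=True)
class ClassPartition:
    """Disjoint meta-training / meta-validation / meta-test class sets."""

    trn_classes: tuple[str, ...]
    val_classes: tuple[str, ...]
    tst_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.trn_classes), set(self.val_classes), set(self.tst_classes)]
        if not all(sets):
            raise PartitionError("each meta-set must contain at least one class")
        if len(set().union(*sets)) != sum(len(s) for s in sets):
            raise PartitionError("meta-sets must be pairwise disjoint")

    @property
    def all_classes(self) -> tuple[str, ...]:
        return self.trn_classes + self.val_classes + self.tst_classes

    def classes_for(self, pool: str) -> tuple[str, ...]:
        return {"trn": self.trn_classes, "val": self.val_classes,
                "tst": self.tst_classes}[pool]

    def to_json(self) -> str:
        return json.dumps(
            {
                "trn_classes": list(self.trn_classes),
                "val_classes": list(self.val_classes),
                "tst_classes": list(self.tst_classes),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassPartition":
        data = json.loads(text)
        return cls(
            tuple(data["trn_classes"]),
            tuple(data["val_classes"]),
            tuple(data["tst_classes"]),
        )


def build_class_partition(
    class_source_counts: pd.DataFrame,
    n_tst: int = 5,
    n_trn: int = 7,
) -> ClassPartition:
    """Build the meta-partition from a class-by-source count matrix.

    Rule: the ``n_tst`` classes with the smallest totals among classes present
    (count > 0) in every source become the meta-test set; of the remaining
    classes ranked by total descending, the top ``n_trn`` become meta-training
    and the rest meta-validation.  Ties are broken by row order of the count
    matrix (vocabulary order), so the result is deterministic and invariant to
    shuffling the input rows.

    The defaults (5, 7) reproduce the published 7 / 3 / 5 partition of the
    15-class corpus.
    """
    counts = class_source_counts
    n_classes = len(counts)
    if n_tst + n_trn >= n_classes:
        raise PartitionError(
            f"n_tst + n_trn = {n_tst + n_trn} leaves no meta-validation class "
            f"for a {n_classes}-class vocabulary"
        )
    # Canonical (vocabulary) order for tie-breaking, regardless of input order.
    vocab_rank = {name: i for i, name in enumerate(counts.index)}
    totals = counts.sum(axis=1)

    everywhere = counts.gt(0).all(axis=1)
    eligible = [c for c in counts.index if everywhere[c]]
    if len(eligible) < n_tst:
        raise PartitionError(
            f"only {len(eligible)} classes present in all sources; "
            f"cannot select {n_tst} meta-test classes"
        )
    eligible.sort(key=lambda c: (totals[c], vocab_rank[c]))
    tst = tuple(eligible[:n_tst])

    remaining = [c for c in counts.index if c not in tst]
    remaining.sort(key=lambda c: (-totals[c], vocab_rank[c]))
    trn = tuple(remaining[:n_trn])
    val = tuple(remaining[n_trn:])
    return ClassPartition(trn_classes=trn, val_classes=val, tst_classes=tst)


@dataclass(frozen=True)
class ExampleSplit:
    """Disjoint per-meta-set example pools (record ids).

    ``*_ids`` hold labeled records, ``*_normal_ids`` the not-finding records
    allocated to each pool; a pool is the union of the two.
    """

    trn_ids: frozenset[str]
    val_ids: frozenset[str]
    tst_ids: frozenset[str]
    trn_normal_ids: frozenset[str]
    val_normal_ids: frozenset[str]
    tst_normal_ids: frozenset[str]

    def labeled(self, pool: str) -> frozenset[str]:
        return {"trn": self.trn_ids, "val": self.val_ids, "tst": self.tst_ids}[pool]

    def normals(self, pool: str) -> frozenset[str]:
        return {
            "trn": self.trn_normal_ids,
            "val": self.val_normal_ids,
            "tst": self.tst_normal_ids,
        }[pool]

    def pool(self, pool: str) -> frozenset[str]:
        return self.labeled(pool) | self.normals(pool)

    def to_json(self) -> str:
        return json.dumps(
            {
                f"{p}{suffix}": sorted(ids)
                for p in POOLS
                for suffix, ids in (
                    ("_ids", self.labeled(p)),
                    ("_normal_ids", self.normals(p)),
                )
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ExampleSplit":
        data = json.loads(text)
        return cls(**{k: frozenset(v) for k, v in data.items()})


def _apportion(n: int, fractions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n items over fractions."""
    exact = fractions * n
    base = np.floor(exact).astype(int)
    leftover = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:leftover]] += 1
    return base


def _seeded_allocation(
    rows: np.ndarray, fractions: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    shuffled = rng.permutation(rows)
    sizes = _apportion(len(rows), fractions)
    return tuple(np.split(shuffled, np.cumsum(sizes)[:-1]))


def split_examples(
    table: MetadataTable,
    partition: ClassPartition,
    normal_fractions: tuple[float, float, float] = DEFAULT_NORMAL_FRACTIONS,
    seen_fractions: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> ExampleSplit:
    """Assign every record to exactly one meta-set pool.

    Labeled records carrying scarce-class labels follow a precedence rule that
    keeps all their positives available for evaluation: any meta-test class
    label sends a record to the meta-test pool; otherwise any meta-validation
    label sends it to the meta-validation pool.  Records labeled only with
    meta-training classes are apportioned across the three pools by
    ``seen_fractions`` (defaulting to ``normal_fractions``): generalized
    evaluation episodes mix seen and unseen classes, so the evaluation pools
    need seen-class examples — both as episode positives and as labeled
    negatives for the unseen classes — that are disjoint from everything
    meta-training episodes can draw.  Not-finding records are likewise
    allocated by ``normal_fractions``.  Both allocations use largest-remainder
    sizes and a seeded shuffle, so the split is reproducible from the seed
    alone.
    """
    fractions = np.asarray(normal_fractions, dtype=float)
    if fractions.shape != (3,) or abs(fractions.sum() - 1.0) > 1e-6:
        raise ValueError("normal_fractions must be three proportions summing to 1")
    seen_frac = (
        fractions
        if seen_fractions is None
        else np.asarray(seen_fractions, dtype=float)
    )
    if seen_frac.shape != (3,) or abs(seen_frac.sum() - 1.0) > 1e-6:
        raise ValueError("seen_fractions must be three proportions summing to 1")

    vocab = table.vocabulary
    matrix = table.label_matrix
    tst_cols = vocab.indices(partition.tst_classes)
    val_cols = vocab.indices(partition.val_classes)
    labeled = matrix.any(axis=1)
    has_tst = matrix[:, tst_cols].any(axis=1)
    has_val = matrix[:, val_cols].any(axis=1)

    tst_mask = labeled & has_tst
    val_mask = labeled & ~has_tst & has_val
    trn_only = np.flatnonzero(labeled & ~has_tst & ~has_val)

    rng = np.random.default_rng(seed)
    trn_s, val_s, tst_s = _seeded_allocation(trn_only, seen_frac, rng)
    trn_n, val_n, tst_n = _seeded_allocation(
        np.flatnonzero(~labeled), fractions, rng
    )

    ids = table.ids
    split = ExampleSplit(
        trn_ids=frozenset(ids[trn_s]),
        val_ids=frozenset(ids[np.flatnonzero(val_mask)]) | frozenset(ids[val_s]),
        tst_ids=frozenset(ids[np.flatnonzero(tst_mask)]) | frozenset(ids[tst_s]),
        trn_normal_ids=frozenset(ids[trn_n]),
        val_normal_ids=frozenset(ids[val_n]),
        tst_normal_ids=frozenset(ids[tst_n]),
    )
    import warnings

    for pool in POOLS:
        if split.labeled(pool) and not split.normals(pool):
            warnings.warn(
                f"pool {pool!r} has labeled records but no not-finding records; "
                "episode generation from it will fail",
                stacklevel=2,
            )
    return split
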
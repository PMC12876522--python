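"""Multi-label metadata model: records, inclusion filters, and label statistics.

The canonical on-disk form is a UTF-8 comma-separated file with one row per
image and columns ``id, source, age, labels, image_path``.  The ``labels``
field holds zero or more pathology names joined by ``|``; an empty field marks
a *not finding* image (no pathology observed).  An empty ``age`` field marks an
incomplete record.

In memory a :class:`MetadataTable` keeps columnar arrays (ids, sources, ages,
and a boolean image-by-class label matrix) so that episode sampling over
hundreds of thousands of rows stays vectorised, while :meth:`MetadataTable.records`
exposes row-wise :class:`ImageRecord` objects for small-scale use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .reference import PATHOLOGIES, SOURCES

LABEL_DELIMITER = "|"

#: Default 15-pathology vocabulary of the combined corpus.
DEFAULT_SOURCES = SOURCES


class ValidationError(ValueError):
    """Raised when metadata violates the vocabulary or uniqueness contracts."""


@dataclass(frozen=True)
class PathologyVocabulary:
    """Ordered list of canonical pathology names.

    The order is significant: it defines label-matrix columns and breaks
    ranking ties deterministically.
    """

    names: tuple[str, ...] = PATHOLOGIES

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) < 2:
            raise ValidationError("vocabulary needs at least 2 classes")
        if len(set(names)) != len(names):
            raise ValidationError("vocabulary names must be unique")
        if any(not n for n in names):
            raise ValidationError("vocabulary names must be non-empty")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown pathology {name!r}") from None

    def indices(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)


DEFAULT_VOCABULARY = PathologyVocabulary()


@dataclass(frozen=True)
class ImageRecord:
    """One image row: identifier, source tag, age, label set, file reference."""

    id: str
    source: str
    age: int | None
    labels: frozenset[str]
    image_path: str | None = None

    @property
    def not_finding(self) -> bool:
        """True iff the record carries no pathology label."""
        return not self.labels


class MetadataTable:
    """Columnar multi-label metadata with a fixed vocabulary.

    Parameters
    ----------
    ids, sources : sequences of str
    ages : sequence of int or None (missing)
    label_matrix : (n_records, n_classes) boolean array
    vocabulary : PathologyVocabulary
    image_paths : optional sequence of str or None
    """

    def __init__(
        self,
        ids: Sequence[str],
        sources: Sequence[str],
        ages: Sequence[int | None],
        label_matrix: np.ndarray,
        vocabulary: PathologyVocabulary = DEFAULT_VOCABULARY,
        image_paths: Sequence[str | None] | None = None,
    ) -> None:
        self.ids = np.asarray(ids, dtype=object)
        self.sources = np.asarray(sources, dtype=object)
        self.ages = np.array([np.nan if a is None else float(a) for a in ages])
        self.label_matrix = np.asarray(label_matrix, dtype=bool)
        self.vocabulary = vocabulary
        if image_paths is None:
            image_paths = [None] * len(self.ids)
        self.image_paths = np.asarray(image_paths, dtype=object)
        n = len(self.ids)
        if self.label_matrix.shape != (n, len(vocabulary)):
            raise ValidationError(
                f"label matrix shape {self.label_matrix.shape} does not match "
                f"{n} records x {len(vocabulary)} classes"
            )
        if len(set(self.ids)) != n:
            dupes = pd.Series(self.ids).value_counts()
            raise ValidationError(
                f"duplicate record ids: {list(dupes[dupes > 1].index[:5])}"
            )
        self._id_index: dict[str, int] | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[ImageRecord],
        vocabulary: PathologyVocabulary = DEFAULT_VOCABULARY,
    ) -> "MetadataTable":
        records = list(records)
        matrix = np.zeros((len(records), len(vocabulary)), dtype=bool)
        for i, rec in enumerate(records):
            for name in rec.labels:
                if name not in vocabulary:
                    raise ValidationError(
                        f"record {rec.id!r}: unknown pathology {name!r}"
                    )
                matrix[i, vocabulary.index(name)] = True
        return cls(
            ids=[r.id for r in records],
            sources=[r.source for r in records],
            ages=[r.age for r in records],
            label_matrix=matrix,
            vocabulary=vocabulary,
            image_paths=[r.image_path for r in records],
        )

    # -- row access --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def not_finding(self) -> np.ndarray:
        """Boolean mask of records with no pathology label."""
        return ~self.label_matrix.any(axis=1)

    def id_index(self) -> dict[str, int]:
        if self._id_index is None:
            self._id_index = {rid: i for i, rid in enumerate(self.ids)}
        return self._id_index

    def rows_for_ids(self, record_ids: Sequence[str]) -> np.ndarray:
        index = self.id_index()
        return np.array([index[r] for r in record_ids], dtype=int)

    def record(self, i: int) -> ImageRecord:
        labels = frozenset(
            name
            for name, on in zip(self.vocabulary.names, self.label_matrix[i])
            if on
        )
        age = None if math.isnan(self.ages[i]) else int(self.ages[i])
        return ImageRecord(
            id=self.ids[i],
            source=self.sources[i],
            age=age,
            labels=labels,
            image_path=self.image_paths[i],
        )

    def records(self) -> Iterator[ImageRecord]:
        for i in range(len(self)):
            yield self.record(i)

    def subset(self, mask_or_rows: np.ndarray) -> "MetadataTable":
        rows = np.asarray(mask_or_rows)
        return MetadataTable(
            ids=self.ids[rows],
            sources=self.sources[rows],
            ages=[None if math.isnan(a) else int(a) for a in self.ages[rows]],
            label_matrix=self.label_matrix[rows],
            vocabulary=self.vocabulary,
            image_paths=self.image_paths[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        labels = [
            LABEL_DELIMITER.join(
                name for name, on in zip(self.vocabulary.names, row) if on
            )
            for row in self.label_matrix
        ]
        ages = ["" if math.isnan(a) else int(a) for a in self.ages]
        return pd.DataFrame(
            {
                "id": self.ids,
                "source": self.sources,
                "age": ages,
                "labels": labels,
                "image_path": [p if p is not None else "" for p in self.image_paths],
            }
        )

    def class_counts(self) -> np.ndarray:
        """Global per-class label-instance counts, vocabulary order."""
        return self.label_matrix.sum(axis=0).astype(int)


# ---------------------------------------------------------------------------
# I/O


REQUIRED_COLUMNS = ("id", "source", "age", "labels")


def read_metadata(
    path,
    vocabulary: PathologyVocabulary = DEFAULT_VOCABULARY,
    delimiter: str = LABEL_DELIMITER,
) -> MetadataTable:
    """Read a metadata CSV into a :class:`MetadataTable`.

    The header must declare ``id, source, age, labels`` (``image_path`` is
    optional).  Unknown pathology names raise :class:`ValidationError` naming
    the offending row; duplicate ids are rejected.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"metadata file missing required columns: {missing}")

    matrix = np.zeros((len(frame), len(vocabulary)), dtype=bool)
    known = {name: i for i, name in enumerate(vocabulary.names)}
    for row, cell in enumerate(frame["labels"]):
        if not cell:
            continue
        for name in cell.split(delimiter):
            col = known.get(name)
            if col is None:
                raise ValidationError(
                    f"row {row} (id={frame['id'].iloc[row]!r}): "
                    f"unknown pathology {name!r}"
                )
            matrix[row, col] = True

    ages = [int(a) if a.strip() else None for a in frame["age"]]
    paths = (
        [p if p else None for p in frame["image_path"]]
        if "image_path" in frame.columns
        else None
    )
    return MetadataTable(
        ids=frame["id"].tolist(),
        sources=frame["source"].tolist(),
        ages=ages,
        label_matrix=matrix,
        vocabulary=vocabulary,
        image_paths=paths,
    )


def write_metadata(table: MetadataTable, path) -> None:
    """Write the canonical CSV form (labels joined by ``|``)."""
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filters


def _image_readable(path: str | None) -> bool:
    if not path:
        return False
    try:
        from PIL import Image

        with Image.open(path) as img:
            img.verify()
        return True
    except Exception:
        return False


def filter_records(
    table: MetadataTable,
    min_age: int = 10,
    max_age: int = 80,
    check_images: bool = False,
) -> MetadataTable:
    """Apply the corpus inclusion filters.

    Retains records with ``min_age <= age <= max_age`` (both endpoints
    inclusive) and complete required fields; records with a missing age or an
    empty id/source are treated as incomplete and dropped.  When
    ``check_images`` is set, records whose image file cannot be opened are
    dropped as corrupted.  Idempotent; an empty result is permitted.
    """
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    mask = (
        ~np.isnan(table.ages)
        & (table.ages >= min_age)
        & (table.ages <= max_age)
        & np.array([bool(i) for i in table.ids])
        & np.array([bool(s) for s in table.sources])
    )
    if check_images:
        mask &= np.array([_image_readable(p) for p in table.image_paths])
    return table.subset(mask)


# ---------------------------------------------------------------------------
# Statistics


def truncate2(value: float) -> float:
    """Truncate (not round) to two decimals, the corpus tables' convention."""
    return math.floor(value * 100.0) / 100.0


@dataclass
class LabelStats:
    """Dataset-level multi-label summary.

    ``cardinality`` is the mean number of labels per *labeled* image
    (``n_instances / n_labeled``); ``density`` divides it by the vocabulary
    size.  Both are ``None`` when no labeled image exists.  ``co_occurrence``
    is a symmetric class-by-class count of label pairs appearing on the same
    record, with a zero diagonal (a class does not co-occur with itself;
    singleton counts live in ``per_class_counts``).
    """

    n_images: int
    n_labeled: int
    n_normal: int
    n_instances: int
    cardinality: float | None
    density: float | None
    per_class_counts: dict[str, int]
    co_occurrence: pd.DataFrame = field(repr=False)

    def to_json(self) -> str:
        payload = {
            "n_images": self.n_images,
            "n_labeled": self.n_labeled,
            "n_normal": self.n_normal,
            "n_instances": self.n_instances,
            "cardinality": self.cardinality,
            "density": self.density,
            "per_class_counts": self.per_class_counts,
        }
        return json.dumps(payload, indent=2)


def label_stats(table: MetadataTable) -> LabelStats:
    """Compute counts, cardinality, density, and pairwise co-occurrence."""
    matrix = table.label_matrix
    n_images = len(table)
    labeled = matrix.any(axis=1)
    n_labeled = int(labeled.sum())
    n_normal = n_images - n_labeled
    per_class = matrix.sum(axis=0).astype(int)
    n_instances = int(per_class.sum())
    if n_labeled > 0:
        cardinality = n_instances / n_labeled
        density = cardinality / len(table.vocabulary)
    else:
        cardinality = density = None
    co = (matrix.astype(np.int64).T @ matrix.astype(np.int64))
    np.fill_diagonal(co, 0)
    names = list(table.vocabulary.names)
    return LabelStats(
        n_images=n_images,
        n_labeled=n_labeled,
        n_normal=n_normal,
        n_instances=n_instances,
        cardinality=cardinality,
        density=density,
        per_class_counts=dict(zip(names, per_class.tolist())),
        co_occurrence=pd.DataFrame(co, index=names, columns=names),
    )


def class_source_counts(table: MetadataTable) -> pd.DataFrame:
    """Label-instance counts by (class, source), vocabulary order rows."""
    sources = sorted(set(table.sources), key=list(table.sources).index)
    counts = pd.DataFrame(
        0, index=list(table.vocabulary.names), columns=sources, dtype=int
    )
    for src in sources:
        rows = table.sources == src
        counts[src] = table.label_matrix[rows].sum(axis=0).astype(int)
    counts.index.name = "class"
    return counts


@dataclass
class BreakdownBlock:
    """One meta-set block of the per-class-per-source census."""

    counts: pd.DataFrame          # classes x sources, plus Total column
    total: int                    # block label-instance total
    source_shares: dict[str, float]  # percent of block total, full precision

    def source_shares_printed(self) -> dict[str, float]:
        """Two-decimal truncated shares, the corpus tables' print convention."""
        return {s: truncate2(v) for s, v in self.source_shares.items()}


def source_breakdown(
    counts_or_table,
    partition,
) -> dict[str, BreakdownBlock]:
    """Per-meta-set census: counts by (class, source), totals, and shares.

    ``counts_or_table`` may be a :class:`MetadataTable` or a precomputed
    class-by-source count DataFrame.  ``partition`` is a
    :class:`gfchest.partition.ClassPartition` covering the classes.
    """
    if isinstance(counts_or_table, MetadataTable):
        counts = class_source_counts(counts_or_table)
    else:
        counts = counts_or_table
    blocks: dict[str, BreakdownBlock] = {}
    for name, classes in (
        ("trn", partition.trn_classes),
        ("val", partition.val_classes),
        ("tst", partition.tst_classes),
    ):
        missing = [c for c in classes if c not in counts.index]
        if missing:
            raise ValidationError(f"partition classes not in counts: {missing}")
        block = counts.loc[list(classes)].copy()
        total = int(block.to_numpy().sum())
        shares = {
            src: (100.0 * block[src].sum() / total) if total else 0.0
            for src in block.columns
        }
        block["Total"] = block.sum(axis=1)
        blocks[name] = BreakdownBlock(counts=block, total=total, source_shares=shares)
    return blocks
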
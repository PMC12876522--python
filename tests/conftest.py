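"""Shared fixtures: hand-built tables, synthetic corpora, and trained models.

Training budgets here are the desk-scale study configuration used throughout
the suite; the heavier session-scoped fixtures are built once and reused.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import gfchest as g
from gfchest.data_model import class_source_counts
from gfchest.synthetic import balanced_benchmark_config, easy_benchmark_config

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


SMALL_VOCAB = g.PathologyVocabulary(("Alpha", "Beta", "Gamma", "Delta"))


def make_record(i, labels=(), source="CheXpert", age=40):
    return g.ImageRecord(
        id=f"r{i:03d}", source=source, age=age, labels=frozenset(labels)
    )


@pytest.fixture
def tiny_table():
    """Six-record toy table over a 4-class vocabulary."""
    records = [
        make_record(0, ["Alpha"]),
        make_record(1, ["Alpha", "Beta"]),
        make_record(2, ["Gamma"], source="MIMIC"),
        make_record(3, [], age=70),
        make_record(4, ["Beta", "Delta"], source="MIMIC", age=25),
        make_record(5, [], source="PadChest"),
    ]
    return g.MetadataTable.from_records(records, SMALL_VOCAB)


@pytest.fixture(scope="session")
def easy_setup():
    """Six-class mildly imbalanced synthetic corpus with partition and split."""
    config = easy_benchmark_config(n_images=12_000, seed=5)
    table = g.make_synthetic_metadata(config)
    part = g.build_class_partition(class_source_counts(table), n_tst=2, n_trn=3)
    split = g.split_examples(table, part, seed=5)
    renderer = g.SyntheticRenderer(config, cache_size=15_000)
    return config, table, part, split, renderer


@pytest.fixture(scope="session")
def balanced_setup():
    """Ten-class synthetic corpus supporting the full episode grid."""
    config = balanced_benchmark_config(n_images=15_000, seed=5)
    table = g.make_synthetic_metadata(config)
    part = g.build_class_partition(class_source_counts(table), n_tst=5, n_trn=4)
    split = g.split_examples(table, part, seed=5)
    renderer = g.SyntheticRenderer(config, cache_size=20_000)
    return config, table, part, split, renderer


PROTONET_DESK = dict(
    episodes_per_epoch=50,
    max_epochs=6,
    patience=3,
    val_episodes=10,
    lr=1e-4,
    train_spec=g.EpisodeSpec(3, 0, 30, 30),
    val_spec=g.EpisodeSpec(2, 1, 5, 5),
    random_state=11,
)

BATCHBASED_DESK = dict(
    examples_per_epoch=3000,
    max_epochs=6,
    patience=3,
    val_episodes=8,
    lr=3e-4,
    val_spec=g.EpisodeSpec(2, 1, 5, 5),
    random_state=11,
)


@pytest.fixture(scope="session")
def protonet_easy(easy_setup):
    _, table, part, split, renderer = easy_setup
    model = g.ProtoNetML(**PROTONET_DESK)
    model.fit(table, split, part, renderer)
    return model


@pytest.fixture(scope="session")
def batchbased_easy(easy_setup):
    _, table, part, split, renderer = easy_setup
    model = g.BatchBased(**BATCHBASED_DESK)
    model.fit(table, split, part, renderer)
    return model


@pytest.fixture(scope="session")
def protonet_balanced(balanced_setup):
    _, table, part, split, renderer = balanced_setup
    model = g.ProtoNetML(**PROTONET_DESK)
    model.fit(table, split, part, renderer)
    return model


@pytest.fixture(scope="session")
def batchbased_balanced(balanced_setup):
    _, table, part, split, renderer = balanced_setup
    model = g.BatchBased(**BATCHBASED_DESK)
    model.fit(table, split, part, renderer)
    return model


def check_episode(episode, table, split, partition, spec):
    """Brute-force re-verification of every episode constraint.

    Independent of the generator: works record by record from the raw label
    sets.  Returns a list of violation strings (empty = valid).
    """
    problems = []
    index = table.id_index()

    def labels_of(rid):
        return table.record(index[rid]).labels

    if len(episode.seen_classes) != spec.n_seen:
        problems.append("wrong number of seen classes")
    if len(episode.unseen_classes) != spec.n_unseen:
        problems.append("wrong number of unseen classes")
    if not set(episode.seen_classes) <= set(partition.trn_classes):
        problems.append("seen classes not from the meta-training class set")
    unseen_home = partition.classes_for(episode.pool if episode.pool != "trn" else "val")
    if not set(episode.unseen_classes) <= set(unseen_home):
        problems.append("unseen classes from the wrong class set")
    expected_excluded = (
        set(table.vocabulary.names)
        - set(episode.seen_classes)
        - set(episode.unseen_classes)
    )
    if set(episode.excluded_classes) != expected_excluded:
        problems.append("excluded set is not the vocabulary complement")

    pool_ids = split.pool(episode.pool)
    for name, ids, k in (
        ("trn", episode.trn_ids, spec.k_trn),
        ("tst", episode.tst_ids, spec.k_tst),
    ):
        if len(set(ids)) != len(ids):
            problems.append(f"{name}: duplicate record ids")
        negatives = 0
        per_class = {c: 0 for c in episode.classes}
        for rid in ids:
            if rid not in pool_ids:
                problems.append(f"{name}: record {rid} outside the {episode.pool} pool")
            labels = labels_of(rid)
            if labels & episode.excluded_classes:
                problems.append(f"{name}: record {rid} carries an excluded class")
            if not labels:
                negatives += 1
            for c in labels:
                per_class[c] += 1
        if negatives < 1:
            problems.append(f"{name}: no not-finding negative")
        for c, count in per_class.items():
            if count < k:
                problems.append(
                    f"{name}: class {c} has {count} positives, needs >= {k}"
                )
    if set(episode.trn_ids) & set(episode.tst_ids):
        problems.append("train/test subsets overlap")
    return problems
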
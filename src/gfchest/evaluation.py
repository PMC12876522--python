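"""Generalized few-shot scoring: pooled AUC-ROC, harmonic mean, aggregation.

Seen and unseen classes are scored separately: all (record, class) label/score
pairs of a class subset are flattened into one binary problem and the area
under its ROC curve is reported on the 0-100 percent scale.  The harmonic mean
of the two penalizes imbalance between seen and unseen performance.  Episode
scores are averaged with a normal-approximation 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .data_model import MetadataTable
from .episodes import Episode, EpisodeSpec, InsufficientDataError, generate_episode


class UndefinedMetricError(ValueError):
    """The pooled labels contain only one class; AUC-ROC is undefined."""


@dataclass(frozen=True)
class PredictionMatrix:
    """Per-(test record, episode class) probabilities in [0, 1]."""

    probs: np.ndarray
    classes: tuple[str, ...]
    record_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (len(self.record_ids), len(self.classes)):
            raise ValueError(
                f"probs shape {probs.shape} does not match "
                f"{len(self.record_ids)} records x {len(self.classes)} classes"
            )
        if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")


def pooled_auc(
    labels: np.ndarray, probs: np.ndarray, class_cols: Sequence[int] | None = None
) -> float:
    """Pooled AUC-ROC over a class subset, as a percent.

    Flattens all (record, class) pairs for the selected columns into a single
    binary problem.  Ties are handled by midranks (the Mann-Whitney
    equivalence), so the result is invariant under strictly monotone
    transforms of the scores.
    """
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    if class_cols is not None:
        labels = labels[:, class_cols]
        probs = probs[:, class_cols]
    y = labels.ravel().astype(int)
    s = probs.ravel()
    if y.min() == y.max():
        raise UndefinedMetricError(
            "pooled labels are single-class; AUC-ROC undefined"
        )
    return float(roc_auc_score(y, s)) * 100.0


def harmonic_mean(seen: float, unseen: float) -> float:
    """Harmonic mean of two non-negative percent scores; 0 if either is 0."""
    if seen < 0 or unseen < 0:
        raise ValueError("scores must be non-negative")
    if seen == 0 or unseen == 0:
        return 0.0
    return 2.0 * seen * unseen / (seen + unseen)


@dataclass(frozen=True)
class EpisodeScores:
    """Seen / unseen pooled AUC-ROC and their harmonic mean, percent scale.

    For all-unseen episodes (no seen class) the seen slot is ``None`` and
    ``hm`` equals ``unseen_auc``, matching the single-value convention used
    for all-unseen rows in benchmark tables; symmetrically for episodes with
    no unseen class, ``hm`` equals ``seen_auc``.
    """

    seen_auc: float | None
    unseen_auc: float | None
    hm: float


def score_episode(
    episode: Episode, predictions: PredictionMatrix, table: MetadataTable
) -> EpisodeScores:
    """Score one episode's predictions on its test subset."""
    if predictions.classes != episode.classes:
        raise ValueError("prediction classes do not match episode classes")
    if predictions.record_ids != episode.tst_ids:
        raise ValueError("prediction rows do not match the episode test subset")
    labels = episode.label_matrix(table, "tst")
    mask = episode.seen_mask()
    seen_cols = np.flatnonzero(mask)
    unseen_cols = np.flatnonzero(~mask)
    seen = (
        pooled_auc(labels, predictions.probs, seen_cols) if len(seen_cols) else None
    )
    unseen = (
        pooled_auc(labels, predictions.probs, unseen_cols)
        if len(unseen_cols)
        else None
    )
    if seen is None:
        hm = unseen
    elif unseen is None:
        hm = seen
    else:
        hm = harmonic_mean(seen, unseen)
    return EpisodeScores(seen_auc=seen, unseen_auc=unseen, hm=hm)


@dataclass
class AggregateReport:
    """Episode-averaged metrics with confidence half-widths."""

    means: dict[str, float]
    half_widths: dict[str, float]
    n_episodes: int
    level: float = 0.95
    grid: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:
        parts = [
            f"{k}={self.means[k]:.2f} ± {self.half_widths[k]:.2f}"
            for k in self.means
        ]
        return f"AggregateReport(n={self.n_episodes}, {', '.join(parts)})"


def aggregate(
    scores: Sequence[EpisodeScores], level: float = 0.95
) -> AggregateReport:
    """Mean and normal-approximation CI half-width per metric.

    Half-width = z(level) * sd / sqrt(n).  Metrics undefined for every episode
    (e.g. seen AUC of an all-unseen sweep) are omitted.
    """
    if not scores:
        raise ValueError("aggregate requires at least one episode score")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    means: dict[str, float] = {}
    hws: dict[str, float] = {}
    for name in ("seen_auc", "unseen_auc", "hm"):
        values = np.array(
            [getattr(s, name) for s in scores if getattr(s, name) is not None]
        )
        if not len(values):
            continue
        means[name] = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        hws[name] = z * sd / np.sqrt(len(values))
    return AggregateReport(
        means=means, half_widths=hws, n_episodes=len(scores), level=level
    )


def run_grid(
    model,
    table: MetadataTable,
    split,
    partition,
    provider,
    ways: Sequence[int] = (3, 4, 5),
    n_unseen_values: Sequence[int] | None = None,
    k_values: Sequence[int] = (30,),
    k_tst: int = 30,
    episodes_per_cell: int = 100,
    pool: str = "tst",
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Sweep (n-way, n-unseen, k_trn) cells and aggregate each.

    ``model`` must expose ``predict_episode(episode, table, provider, rng)``
    returning a :class:`PredictionMatrix` (both bundled methods do).  A cell
    whose pool cannot supply its episodes is marked skipped with the reason.
    Returns one row per cell with per-metric means and half-widths.
    """
    rows = []
    for way in ways:
        unseens = n_unseen_values if n_unseen_values is not None else range(1, way + 1)
        for n_unseen in unseens:
            if n_unseen > way:
                continue
            for k in k_values:
                cell_seed = np.random.SeedSequence(
                    entropy=seed, spawn_key=(way, n_unseen, k)
                )
                rng = np.random.default_rng(cell_seed)
                spec = EpisodeSpec(
                    n_seen=way - n_unseen, n_unseen=n_unseen, k_trn=k, k_tst=k_tst
                )
                row = {"n_way": way, "n_unseen": n_unseen, "k_trn": k}
                try:
                    scores = []
                    for _ in range(episodes_per_cell):
                        episode = generate_episode(
                            table, split, partition, spec, rng, pool=pool
                        )
                        pred = model.predict_episode(episode, table, provider, rng=rng)
                        scores.append(score_episode(episode, pred, table))
                    report = aggregate(scores, level=level)
                    for name, value in report.means.items():
                        row[name] = value
                        row[f"{name}_hw"] = report.half_widths[name]
                    row["n_episodes"] = report.n_episodes
                    row["skipped"] = ""
                except InsufficientDataError as exc:
                    row["n_episodes"] = 0
                    row["skipped"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def report_to_markdown(frame: pd.DataFrame) -> str:
    """Render a grid report as a compact Markdown table."""
    lines = ["| n-way | n-unseen | k_trn | Seen | Unseen | HM |",
             "|---|---|---|---|---|---|"]
    for _, row in frame.iterrows():
        if row.get("skipped"):
            cells = ["skipped"] * 3
        else:
            cells = [
                f"{row[m]:.2f} ± {row[m + '_hw']:.2f}" if m in row and pd.notna(row.get(m)) else "—"
                for m in ("seen_auc", "unseen_auc", "hm")
            ]
        lines.append(
            f"| {row['n_way']} | {row['n_unseen']} | {row['k_trn']} | "
            + " | ".join(cells) + " |"
        )
    return "\n".join(lines)
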
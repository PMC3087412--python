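"""Content-based retrieval evaluation on top of the nearness measures.

A database is a mapping ``image_id -> list of perceptual objects`` (one
object per subimage).  Retrieval ranks the database by the tNM or tHD
value between the query's object set and each entry's, in descending
order.  Evaluation follows standard image-retrieval practice:
precision/recall at every cutoff, the count of same-category images
retrieved before the first other-category image, and — for tolerance
selection — the count retrieved before precision drops below a floor,
swept over a grid of epsilon values.  The pairwise *nearness matrix*
renders the same information as a grayscale "checkerboard": white for
measure 1, black for 0, with a white diagonal from self-comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image

from .classes import find_classes_chaining
from .measures import nearness
from .perceptual import PerceptualObject

__all__ = [
    "RetrievalReport",
    "NearnessMatrix",
    "EpsilonSweepResult",
    "pair_measure",
    "rank_database",
    "precision_recall",
    "average_precision",
    "epsilon_sweep",
    "nearness_matrix",
]

#: Tolerance grid used for epsilon selection sweeps.
DEFAULT_EPSILON_GRID = (0.01, 0.03, 0.05, 0.07, 0.09, 0.1, 0.2, 0.3)
#: Precision floor used for the retrieved-before-floor count.
DEFAULT_PRECISION_FLOOR = 0.9


def _relabel(objects: Sequence[PerceptualObject], prefix: str) -> list[PerceptualObject]:
    return [
        PerceptualObject(
            id=f"{prefix}::{o.id}",
            set_label=prefix,
            description=o.description,
            origin=o.origin,
        )
        for o in objects
    ]


def pair_measure(
    a: Sequence[PerceptualObject],
    b: Sequence[PerceptualObject],
    epsilon: float,
    measure: str = "tnm",
) -> float:
    """tNM or tHD between two object sets, made id-disjoint by relabelling.

    Relabelling lets an image be compared against (a copy of) itself —
    the self-comparison that anchors the matrix diagonal at 1.
    """
    if measure not in ("tnm", "thd"):
        raise ValueError(f"measure must be 'tnm' or 'thd', got {measure!r}")
    X = _relabel(a, "X")
    Y = _relabel(b, "Y")
    cover = find_classes_chaining(X + Y, epsilon)
    result = nearness(X, Y, epsilon, cover=cover, measures=(measure,))
    return result.tnm if measure == "tnm" else result.thd


@dataclass
class RetrievalReport:
    """Ranked database for one query plus the derived evaluation curves."""

    query_id: str
    epsilon: float
    measure: str
    ranked: list[tuple[str, float]]  # (image_id, value), descending
    categories: dict[str, str] = field(default_factory=dict)
    query_category: str | None = None
    precision_at_k: np.ndarray | None = None
    recall_at_k: np.ndarray | None = None
    retrieved_before_miss: int | None = None

    def relevance(self) -> np.ndarray:
        if self.query_category is None:
            raise ValueError("no category labels attached to this report")
        return np.array(
            [self.categories[i] == self.query_category for i, _ in self.ranked],
            dtype=bool,
        )


def rank_database(
    query: Sequence[PerceptualObject],
    database: Mapping[str, Sequence[PerceptualObject]],
    epsilon: float,
    measure: str = "tnm",
    labels: Mapping[str, str] | None = None,
    query_id: str = "query",
    query_category: str | None = None,
) -> RetrievalReport:
    """Rank every database entry by its measure value against the query.

    Descending by value, ties broken by ascending image id.  When
    `labels` are supplied the precision/recall curves and the count of
    same-category images retrieved before the first other-category
    image are filled in.
    """
    if not database:
        raise ValueError("empty database")
    if not query:
        raise ValueError("empty query object set")
    values = {
        image_id: pair_measure(query, objs, epsilon, measure)
        for image_id, objs in database.items()
    }
    ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    report = RetrievalReport(
        query_id=query_id,
        epsilon=float(epsilon),
        measure=measure,
        ranked=ranked,
        categories=dict(labels) if labels else {},
        query_category=query_category,
    )
    if labels is not None and query_category is not None:
        precision_recall(report)
        rel = report.relevance()
        miss = int(np.argmin(rel)) if not rel.all() else len(rel)
        report.retrieved_before_miss = miss
    return report


def precision_recall(report: RetrievalReport) -> tuple[np.ndarray, np.ndarray]:
    """Precision@k and recall@k for k = 1..database size (in place too)."""
    rel = report.relevance()
    total_relevant = int(rel.sum())
    if total_relevant == 0:
        raise ValueError(
            f"query category {report.query_category!r} absent from the database; "
            "recall is degenerate"
        )
    hits = np.cumsum(rel)
    k = np.arange(1, len(rel) + 1)
    report.precision_at_k = hits / k
    report.recall_at_k = hits / total_relevant
    return report.precision_at_k, report.recall_at_k


def average_precision(report: RetrievalReport) -> float:
    """Mean of precision@k over the ranks k holding relevant items."""
    if report.precision_at_k is None:
        precision_recall(report)
    rel = report.relevance()
    return float(report.precision_at_k[rel].mean())


def precision_at_full_recall(report: RetrievalReport) -> float:
    """Precision at the first rank where recall reaches 1."""
    if report.recall_at_k is None:
        precision_recall(report)
    k = int(np.argmax(report.recall_at_k >= 1.0))
    return float(report.precision_at_k[k])


@dataclass
class NearnessMatrix:
    """Symmetric pairwise measure values with a unit self-comparison diagonal."""

    ids: list[str]
    values: np.ndarray
    epsilon: float
    measure: str

    def to_png(self, path: str | Path, scale: int = 4) -> None:
        """8-bit grayscale rendering: 0 -> black, 1 -> white."""
        img = np.kron(np.clip(self.values, 0.0, 1.0), np.ones((scale, scale)))
        Image.fromarray((img * 255).astype(np.uint8), mode="L").save(path)

    def block_means(self, labels: Mapping[str, str]) -> dict[tuple[str, str], float]:
        """Mean measure per (category, category) block, off-diagonal entries only."""
        cats = sorted(set(labels.values()))
        idx = {c: [i for i, im in enumerate(self.ids) if labels[im] == c] for c in cats}
        out = {}
        for a in cats:
            for b in cats:
                vals = [
                    self.values[i, j]
                    for i in idx[a]
                    for j in idx[b]
                    if i != j
                ]
                out[(a, b)] = float(np.mean(vals))
        return out


def nearness_matrix(
    database: Mapping[str, Sequence[PerceptualObject]],
    epsilon: float,
    measure: str = "tnm",
) -> NearnessMatrix:
    """All-pairs measure matrix; self-pairs use a relabelled duplicate set."""
    if not database:
        raise ValueError("empty database")
    ids = list(database.keys())
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = pair_measure(database[ids[i]], database[ids[i]], epsilon, measure)
        for j in range(i + 1, n):
            v = pair_measure(database[ids[i]], database[ids[j]], epsilon, measure)
            values[i, j] = values[j, i] = v
    return NearnessMatrix(ids=ids, values=values, epsilon=float(epsilon), measure=measure)


@dataclass
class EpsilonEntry:
    """Sweep outcome at one tolerance."""

    epsilon: float
    matrix: NearnessMatrix
    counts: dict[str, int]  # per query: retrieved before precision < floor
    mean_count: float
    best_count: int
    best_query: str
    per_category_mean_count: dict[str, float]
    mean_average_precision: float
    mean_precision_at_full_recall: float


@dataclass
class EpsilonSweepResult:
    entries: list[EpsilonEntry]
    precision_floor: float
    measure: str

    @property
    def best_epsilon(self) -> float:
        """Argmax of the mean retrieved-before-floor count (ties -> smaller ε)."""
        best = max(self.entries, key=lambda e: (e.mean_count, -e.epsilon))
        return best.epsilon


def report_from_matrix(
    matrix: NearnessMatrix,
    query_id: str,
    labels: Mapping[str, str],
) -> RetrievalReport:
    """Derive one query's retrieval report from a stored pairwise matrix."""
    qi = matrix.ids.index(query_id)
    pairs = [
        (im, float(matrix.values[qi, j]))
        for j, im in enumerate(matrix.ids)
        if im != query_id
    ]
    ranked = sorted(pairs, key=lambda kv: (-kv[1], kv[0]))
    report = RetrievalReport(
        query_id=query_id,
        epsilon=matrix.epsilon,
        measure=matrix.measure,
        ranked=ranked,
        categories=dict(labels),
        query_category=labels[query_id],
    )
    precision_recall(report)
    rel = report.relevance()
    report.retrieved_before_miss = int(np.argmin(rel)) if not rel.all() else len(rel)
    return report


def _count_before_floor(report: RetrievalReport, floor: float) -> int:
    below = report.precision_at_k < floor
    return int(np.argmax(below)) if below.any() else len(report.ranked)


def epsilon_sweep(
    database: Mapping[str, Sequence[PerceptualObject]],
    labels: Mapping[str, str],
    epsilons: Sequence[float] = DEFAULT_EPSILON_GRID,
    measure: str = "tnm",
    precision_floor: float = DEFAULT_PRECISION_FLOOR,
) -> EpsilonSweepResult:
    """Tolerance selection: sweep ε, scoring retrieval quality at each.

    Every database image serves in turn as the query against the rest
    (rankings are read off one stored pairwise matrix per ε).  For each
    ε the per-query count of images retrieved before precision drops
    below `precision_floor` is recorded, with its mean (overall and per
    category) and best query, alongside mean average precision.
    """
    if len(set(labels.values())) < 2:
        raise ValueError("epsilon sweep needs at least two categories")
    if not epsilons:
        raise ValueError("empty epsilon grid")
    entries = []
    for eps in epsilons:
        matrix = nearness_matrix(database, eps, measure)
        counts: dict[str, int] = {}
        aps, pfrs = [], []
        for image_id in matrix.ids:
            report = report_from_matrix(matrix, image_id, labels)
            counts[image_id] = _count_before_floor(report, precision_floor)
            aps.append(average_precision(report))
            pfrs.append(precision_at_full_recall(report))
        best_query = max(counts, key=lambda q: (counts[q], q))
        cats = sorted(set(labels.values()))
        per_cat = {
            c: float(np.mean([counts[q] for q in counts if labels[q] == c]))
            for c in cats
        }
        entries.append(
            EpsilonEntry(
                epsilon=float(eps),
                matrix=matrix,
                counts=counts,
                mean_count=float(np.mean(list(counts.values()))),
                best_count=counts[best_query],
                best_query=best_query,
                per_category_mean_count=per_cat,
                mean_average_precision=float(np.mean(aps)),
                mean_precision_at_full_recall=float(np.mean(pfrs)),
            )
        )
    return EpsilonSweepResult(
        entries=entries, precision_floor=precision_floor, measure=measure
    )
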
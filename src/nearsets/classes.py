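"""Tolerance-class enumeration.

A *preclass* is a set of objects that are pairwise tolerance related; a
*tolerance class* is a preclass that is maximal with respect to
inclusion.  Equivalently, tolerance classes are exactly the maximal
cliques of the tolerance graph whose edges join objects within
``epsilon`` of each other.

Two enumeration routes are provided:

:func:`find_classes_chaining`
    The neighbourhood-chaining algorithm.  For each object ``z`` it
    computes the neighbourhood ``N(z)`` — a superset of every tolerance
    class containing ``z`` — and then grows preclasses by repeatedly
    querying the nearest remaining neighbour inside the shrinking
    intersection of neighbourhoods, until a query's neighbourhood
    contains only the query itself, at which point the chain of query
    points is a maximal preclass.  An optional heuristic (on by
    default) skips chain starts that already landed in a class derived
    from the same ``N(z)``, trading completeness for speed.

:func:`find_classes_exact`
    An exact oracle for validation at desk scale: all maximal cliques
    of the tolerance graph via Bron–Kerbosch.

The chaining route always emits valid, maximal classes, but whether it
emits *every* maximal preclass is measured against the exact oracle
rather than assumed; see :func:`completeness_report`.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from numba import njit

from .perceptual import BOUNDARY_SLACK, PerceptualObject, description_matrix

__all__ = [
    "ToleranceClass",
    "ClassCover",
    "find_classes_chaining",
    "find_classes_exact",
    "is_preclass",
    "completeness_report",
]

#: Largest input size accepted by the exact (Bron–Kerbosch) route.
EXACT_GUARD = 200


@dataclass(frozen=True)
class ToleranceClass:
    """A maximal set of pairwise-``epsilon``-similar objects."""

    member_ids: frozenset[str]
    epsilon: float

    def __len__(self) -> int:
        return len(self.member_ids)

    def sorted_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.member_ids))


@dataclass
class ClassCover:
    """A family of tolerance classes covering a universe of objects.

    ``mode`` records the construction route: ``"heuristic"`` for the
    neighbourhood-chaining algorithm (with or without its skip
    heuristic) and ``"exact"`` for Bron–Kerbosch enumeration.
    """

    classes: list[ToleranceClass]
    universe_ids: frozenset[str]
    epsilon: float
    mode: str

    def __post_init__(self) -> None:
        covered = set()
        for c in self.classes:
            covered |= c.member_ids
        missing = self.universe_ids - covered
        if missing:
            raise ValueError(f"cover misses objects: {sorted(missing)[:5]} ...")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def as_id_sets(self) -> set[tuple[str, ...]]:
        return {c.sorted_ids() for c in self.classes}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "epsilon": self.epsilon,
            "mode": self.mode,
            "classes": [list(c.sorted_ids()) for c in self.classes],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _dedup(families: Iterable[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Deduplicate classes by hashing the sorted member tuple."""
    return sorted(set(families))


def _adjacency(mat: np.ndarray, epsilon: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean tolerance adjacency (reflexive) and the distance matrix."""
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return dist <= epsilon + BOUNDARY_SLACK, dist


def find_classes_chaining(
    objects: Sequence[PerceptualObject],
    epsilon: float,
    use_heuristic: bool = True,
) -> ClassCover:
    """Enumerate tolerance classes by neighbourhood chaining.

    For every object ``z`` the neighbourhood ``N(z)`` is found; a chain
    is started at each eligible ``z' in N(z)`` and extended by always
    querying the nearest remaining neighbour of the current query point
    (ties broken by ascending object id), with each query's
    neighbourhood computed only inside the previous one and query
    points excluded from subsequent neighbourhoods.  When a query's
    neighbourhood holds no further object, the chain of query points is
    a tolerance class.  Duplicates are removed by hashing sorted member
    tuples.

    With ``use_heuristic`` (the default) an object of ``N(z)`` is not
    used as a chain start if it was already placed in a class derived
    from the same ``N(z)``; this prunes redundant chains at a possible
    cost in completeness, which :func:`completeness_report` measures.

    At ``epsilon == 0`` the enumeration short-circuits to the partition
    of objects by exact description equality.
    """
    objects = list(objects)
    if not objects:
        raise ValueError("cannot enumerate classes of an empty object collection")
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    ids, mat = description_matrix(objects)
    if len(set(ids)) != len(ids):
        raise ValueError("object ids must be unique")

    if epsilon == 0:
        # Degenerate case: classes are the equivalence classes of exact
        # description equality, found by a single grouping pass.
        groups: dict[bytes, list[int]] = {}
        for i, row in enumerate(mat):
            groups.setdefault(row.tobytes(), []).append(i)
        families = _dedup(tuple(sorted(g)) for g in groups.values())
        return _build_cover(families, ids, epsilon, "heuristic")

    adj, dist = _adjacency(mat, epsilon)
    n = len(ids)
    if adj.all():
        # every pair is tolerance related: the whole set is the one class
        return _build_cover([tuple(range(n))], ids, epsilon, "heuristic")
    # Id-rank tie-break: lexicographic rank of each id.
    id_rank = np.empty(n, dtype=np.int64)
    for rank, i in enumerate(sorted(range(n), key=lambda i: ids[i])):
        id_rank[i] = rank
    # order[i] = columns sorted by (distance from i, id); rank[i, j] = the
    # position of j in that order, so the nearest remaining neighbour of i
    # is the pool member minimizing rank[i].
    order = np.empty((n, n), dtype=np.int64)
    rank = np.empty((n, n), dtype=np.int64)
    cols = np.arange(n)
    for i in range(n):
        order[i] = np.lexsort((id_rank, dist[i]))
        rank[i, order[i]] = cols

    cap = 64 * n
    while True:
        members = np.empty(cap, dtype=np.int64)
        offsets = np.zeros(cap + 1, dtype=np.int64)
        n_classes, used = _chain_kernel(adj, rank, order, use_heuristic, members, offsets)
        if n_classes >= 0:
            break
        cap *= 4  # buffer overflow: retry with more room
    families = _dedup(
        tuple(sorted(members[offsets[i] : offsets[i + 1]].tolist()))
        for i in range(n_classes)
    )
    return _build_cover(families, ids, epsilon, "heuristic")


@njit(cache=True)
def _chain_kernel(adj, rank, order, use_heuristic, members, offsets):  # pragma: no cover
    """Run the chaining loops for every anchor; emit classes flattened.

    Returns ``(n_classes, n_members_used)``, or ``(-1, -1)`` when the
    output buffers are too small and the caller must retry larger.
    """
    n = adj.shape[0]
    cap = members.shape[0]
    max_classes = offsets.shape[0] - 1
    pool = np.zeros(n, np.bool_)
    placed = np.zeros(n, np.bool_)
    chain = np.empty(n, np.int64)
    pos = 0
    n_classes = 0
    for z in range(n):
        deg = 0
        for j in range(n):
            if adj[z, j]:
                deg += 1
        if deg == 1:  # isolated object: a singleton class
            if pos + 1 > cap or n_classes + 1 > max_classes:
                return -1, -1
            members[pos] = z
            pos += 1
            n_classes += 1
            offsets[n_classes] = pos
            continue
        for j in range(n):
            placed[j] = False
        # step-2 starts in ascending (distance from z, id) order
        for s in range(n):
            zp = order[z, s]
            if zp == z or not adj[z, zp]:
                continue
            if use_heuristic and placed[zp]:
                continue
            for j in range(n):
                pool[j] = adj[z, j]
            pool[z] = False  # "do not include z in N(z')"
            chain[0] = z
            chain[1] = zp
            m = 2
            cur = zp
            while True:
                best = -1
                best_rank = n
                for j in range(n):
                    if pool[j]:
                        if j == cur or not adj[cur, j]:
                            pool[j] = False
                        elif rank[cur, j] < best_rank:
                            best_rank = rank[cur, j]
                            best = j
                if best == -1:
                    break
                chain[m] = best
                m += 1
                cur = best
            if pos + m > cap or n_classes + 1 > max_classes:
                return -1, -1
            for t in range(m):
                members[pos + t] = chain[t]
                if use_heuristic:
                    placed[chain[t]] = True
            pos += m
            n_classes += 1
            offsets[n_classes] = pos
    return n_classes, pos


def find_classes_exact(
    objects: Sequence[PerceptualObject],
    epsilon: float,
) -> ClassCover:
    """All maximal cliques of the tolerance graph (Bron–Kerbosch).

    Guarded to at most :data:`EXACT_GUARD` objects; this route is the
    validation oracle, not the production path.
    """
    objects = list(objects)
    if not objects:
        raise ValueError("cannot enumerate classes of an empty object collection")
    if len(objects) > EXACT_GUARD:
        raise ValueError(
            f"exact enumeration guarded to {EXACT_GUARD} objects, got {len(objects)}"
        )
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    ids, mat = description_matrix(objects)
    if len(set(ids)) != len(ids):
        raise ValueError("object ids must be unique")
    adj, _ = _adjacency(mat, epsilon)
    g = nx.Graph()
    g.add_nodes_from(range(len(ids)))
    iu, ju = np.nonzero(np.triu(adj, k=1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    families = _dedup(tuple(sorted(c)) for c in nx.find_cliques(g))
    return _build_cover(families, ids, epsilon, "exact")


def _build_cover(
    families: Iterable[tuple[int, ...]],
    ids: list[str],
    epsilon: float,
    mode: str,
) -> ClassCover:
    classes = [
        ToleranceClass(member_ids=frozenset(ids[i] for i in fam), epsilon=float(epsilon))
        for fam in families
    ]
    return ClassCover(
        classes=classes,
        universe_ids=frozenset(ids),
        epsilon=float(epsilon),
        mode=mode,
    )


def is_preclass(
    member_ids: Iterable[str],
    objects: Sequence[PerceptualObject],
    epsilon: float,
) -> bool:
    """True iff every pair of the named members is tolerance related."""
    by_id = {o.id: o for o in objects}
    members = list(member_ids)
    unknown = [m for m in members if m not in by_id]
    if unknown:
        raise KeyError(f"unknown object ids: {unknown[:5]}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    mat = np.asarray([by_id[m].description for m in members], dtype=float)
    if mat.size == 0:
        return True
    adj, _ = _adjacency(mat, epsilon)
    return bool(adj.all())


def completeness_report(
    objects: Sequence[PerceptualObject],
    epsilon: float,
    use_heuristic: bool = False,
) -> dict:
    """Compare chaining output against the exact maximal-clique family.

    Returns counts of classes found by each route, how many exact
    classes the chaining route missed, and whether every chaining class
    is itself an exact maximal clique (soundness).
    """
    chain = find_classes_chaining(objects, epsilon, use_heuristic=use_heuristic)
    exact = find_classes_exact(objects, epsilon)
    chain_sets = chain.as_id_sets()
    exact_sets = exact.as_id_sets()
    return {
        "epsilon": float(epsilon),
        "n_objects": len(objects),
        "n_chaining": len(chain_sets),
        "n_exact": len(exact_sets),
        "n_missed": len(exact_sets - chain_sets),
        "sound": chain_sets <= exact_sets,
    }
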
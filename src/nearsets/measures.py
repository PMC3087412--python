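"""Resemblance measures between disjoint object sets.

Both measures aggregate over the tolerance classes of the union
``Z = X ∪ Y``:

tNM (tolerance nearness measure)
    The class-size-weighted average of ``min(|C∩X|, |C∩Y|) /
    max(|C∩X|, |C∩Y|)`` over the classes ``C`` of the cover.  Similar
    sets produce classes that split evenly between ``X`` and ``Y``, so
    each fraction — and hence the weighted average — approaches 1.
    Classes lying wholly inside one set contribute 0.

tHD (tolerance Hausdorff measure)
    The class-size-weighted average of ``L − d_H(C∩X, C∩Y)`` where
    ``d_H`` is the Hausdorff distance between the class portions in
    feature space and ``L`` is the largest attainable distance.
    Following the source formulation, ``L`` defaults to the feature
    count ``l``; the tight L2 diameter ``sqrt(l)`` of the unit cube is
    available via ``largest_distance="sqrt"``.  The reported value is
    additionally divided by ``L`` so that 1 means identical; the raw
    ``[0, L]``-scale value is exposed alongside.  A class with an empty
    ``X``- or ``Y``-portion leaves the Hausdorff distance undefined and
    is treated as maximally distant, contributing ``L − L = 0`` — the
    same zero contribution tNM gives it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .classes import ClassCover, find_classes_chaining
from .perceptual import PerceptualObject

__all__ = [
    "ClassContribution",
    "NearnessResult",
    "tnm",
    "hausdorff",
    "thd",
    "nearness",
]


@dataclass(frozen=True)
class ClassContribution:
    """Bookkeeping for one tolerance class in a measure computation."""

    size: int
    n_x: int
    n_y: int
    fraction: float  # min/max split fraction; 0 when one side is empty
    d_h: float | None = None  # per-class Hausdorff distance; None if undefined


@dataclass
class NearnessResult:
    """Outcome of a tNM and/or tHD evaluation on one set pair."""

    epsilon: float
    tnm: float | None = None
    thd: float | None = None
    thd_raw: float | None = None
    largest_distance: float | None = None
    per_class: list[ClassContribution] = field(default_factory=list)

    @property
    def total_weight(self) -> int:
        return sum(c.size for c in self.per_class)


def _check_pair(
    X: Sequence[PerceptualObject],
    Y: Sequence[PerceptualObject],
    epsilon: float,
    cover: ClassCover | None,
) -> tuple[list[PerceptualObject], list[PerceptualObject], ClassCover]:
    X, Y = list(X), list(Y)
    if not X or not Y:
        raise ValueError("both object sets must be non-empty")
    x_ids = {o.id for o in X}
    y_ids = {o.id for o in Y}
    if x_ids & y_ids:
        raise ValueError(
            f"X and Y must be disjoint by id; shared: {sorted(x_ids & y_ids)[:5]}"
        )
    if cover is None:
        cover = find_classes_chaining(X + Y, epsilon)
    else:
        if not cover.classes:
            raise ValueError("empty class cover")
        if cover.epsilon != epsilon:
            raise ValueError(
                f"cover was built at epsilon={cover.epsilon}, measure asked at {epsilon}"
            )
        if cover.universe_ids != x_ids | y_ids:
            raise ValueError("cover universe does not match X ∪ Y")
    return X, Y, cover


def hausdorff(
    A: Sequence[PerceptualObject] | np.ndarray,
    B: Sequence[PerceptualObject] | np.ndarray,
) -> float:
    """Hausdorff distance between two non-empty description sets (L2).

    ``max`` of the two directed sup-inf distances; symmetric; zero iff
    the description multisets cover each other exactly.
    """
    if len(A) == 0 or len(B) == 0:
        raise ValueError("Hausdorff distance is undefined for an empty set")
    ua = _as_matrix(A)
    ub = _as_matrix(B)
    if ua.shape[0] == 0 or ub.shape[0] == 0:
        raise ValueError("Hausdorff distance is undefined for an empty set")
    d_ab = directed_hausdorff(ua, ub)[0]
    d_ba = directed_hausdorff(ub, ua)[0]
    return float(max(d_ab, d_ba))


def _as_matrix(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return np.atleast_2d(points.astype(float))
    return np.asarray([o.description for o in points], dtype=float).reshape(
        len(points), -1
    )


def _split_counts(
    cover: ClassCover, x_ids: set, desc: dict
) -> Iterable[tuple[int, int, int, np.ndarray, np.ndarray]]:
    for c in cover:
        members = c.member_ids
        mx = [m for m in members if m in x_ids]
        my = [m for m in members if m not in x_ids]
        yield (
            len(members),
            len(mx),
            len(my),
            np.asarray([desc[m] for m in mx], dtype=float),
            np.asarray([desc[m] for m in my], dtype=float),
        )


def nearness(
    X: Sequence[PerceptualObject],
    Y: Sequence[PerceptualObject],
    epsilon: float,
    cover: ClassCover | None = None,
    measures: tuple[str, ...] = ("tnm", "thd"),
    largest_distance: str | float = "l",
) -> NearnessResult:
    """Evaluate tNM and/or tHD on ``X`` vs ``Y`` over one shared cover.

    If `cover` is omitted, tolerance classes of ``Z = X ∪ Y`` are
    enumerated by neighbourhood chaining at the same `epsilon`.
    """
    X, Y, cover = _check_pair(X, Y, epsilon, cover)
    want_thd = "thd" in measures
    want_tnm = "tnm" in measures
    l = X[0].l
    if largest_distance == "l":
        big = float(l)
    elif largest_distance == "sqrt":
        big = float(np.sqrt(l))
    else:
        big = float(largest_distance)

    x_ids = {o.id for o in X}
    desc = {o.id: o.description for o in X + Y}

    contribs: list[ClassContribution] = []
    num_tnm = 0.0
    num_thd = 0.0
    total = 0
    for size, nx_, ny_, dx, dy in _split_counts(cover, x_ids, desc):
        frac = min(nx_, ny_) / max(nx_, ny_) if nx_ and ny_ else 0.0
        d_h: float | None = None
        if want_thd:
            if nx_ and ny_:
                d_h = hausdorff(dx, dy)
                num_thd += size * (big - d_h)
            # empty side: treated as maximally distant, contributes 0
        num_tnm += size * frac
        total += size
        contribs.append(
            ClassContribution(size=size, n_x=nx_, n_y=ny_, fraction=frac, d_h=d_h)
        )

    result = NearnessResult(
        epsilon=float(epsilon),
        largest_distance=big if want_thd else None,
        per_class=contribs,
    )
    if want_tnm:
        result.tnm = num_tnm / total
    if want_thd:
        result.thd_raw = num_thd / total
        result.thd = result.thd_raw / big
    return result


def tnm(
    X: Sequence[PerceptualObject],
    Y: Sequence[PerceptualObject],
    epsilon: float,
    cover: ClassCover | None = None,
) -> NearnessResult:
    """Tolerance nearness measure of ``X`` vs ``Y`` (value in ``[0, 1]``)."""
    return nearness(X, Y, epsilon, cover=cover, measures=("tnm",))


def thd(
    X: Sequence[PerceptualObject],
    Y: Sequence[PerceptualObject],
    epsilon: float,
    cover: ClassCover | None = None,
    largest_distance: str | float = "l",
) -> NearnessResult:
    """Tolerance Hausdorff measure of ``X`` vs ``Y``.

    The ``thd`` field is normalized to ``[0, 1]`` (1 = identical);
    ``thd_raw`` keeps the ``[0, L]`` scale of the weighted sum.
    """
    return nearness(
        X, Y, epsilon, cover=cover, measures=("thd",), largest_distance=largest_distance
    )
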
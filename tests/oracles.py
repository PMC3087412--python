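"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — double loops, exhaustive
subset growth — and shares no code with the package's computation
paths beyond the object container.
"""

from __future__ import annotations

import math
from itertools import combinations

from nearsets import PerceptualObject


def l2(a: PerceptualObject, b: PerceptualObject) -> float:
    return math.sqrt(
        sum((x - y) ** 2 for x, y in zip(a.description, b.description))
    )


def related_matrix(objects, epsilon, slack=1e-12):
    n = len(objects)
    rel = [[l2(objects[i], objects[j]) <= epsilon + slack for j in range(n)] for i in range(n)]
    return rel


def brute_neighbourhood(anchor, pool, epsilon):
    """Exhaustive distance scan."""
    return {o.id for o in pool if l2(anchor, o) <= epsilon + 1e-12}


def naive_maximal_preclasses(objects, epsilon):
    """All maximal pairwise-related subsets by exhaustive subset growth.

    Grows every preclass one member at a time from singletons and keeps
    the ones that cannot be extended.  Exponential; for tiny n only.
    """
    n = len(objects)
    rel = related_matrix(objects, epsilon)
    frontier = {frozenset([i]) for i in range(n)}
    seen = set(frontier)
    maximal = set()
    while frontier:
        grown = set()
        for s in frontier:
            extensions = [
                v for v in range(n) if v not in s and all(rel[v][u] for u in s)
            ]
            if not extensions:
                maximal.add(s)
            else:
                for v in extensions:
                    t = s | {v}
                    if t not in seen:
                        seen.add(t)
                        grown.add(t)
        frontier = grown
    ids = [o.id for o in objects]
    return {tuple(sorted(ids[i] for i in s)) for s in maximal}


def brute_hausdorff(A, B):
    """Double-loop sup-inf in both directions."""
    def directed(P, Q):
        return max(min(l2(p, q) for q in Q) for p in P)

    return max(directed(A, B), directed(B, A))


def direct_tnm(X, Y, cover):
    """Term-by-term direct weighted-average of split fractions."""
    x_ids = {o.id for o in X}
    num = 0.0
    den = 0
    for c in cover:
        nx = sum(1 for m in c.member_ids if m in x_ids)
        ny = len(c.member_ids) - nx
        den += len(c.member_ids)
        if nx and ny:
            num += len(c.member_ids) * min(nx, ny) / max(nx, ny)
    return num / den


def direct_thd(X, Y, cover, big):
    """Term-by-term direct weighted-average of (big - Hausdorff)."""
    by_id = {o.id: o for o in list(X) + list(Y)}
    x_ids = {o.id for o in X}
    num = 0.0
    den = 0
    for c in cover:
        mx = [by_id[m] for m in c.member_ids if m in x_ids]
        my = [by_id[m] for m in c.member_ids if m not in x_ids]
        den += len(c.member_ids)
        if mx and my:
            num += len(c.member_ids) * (big - brute_hausdorff(mx, my))
    return num / den / big


def disjoint_copy(objects, prefix="copy"):
    """Same descriptions, fresh ids and set label."""
    return [
        PerceptualObject(
            id=f"{prefix}::{o.id}",
            set_label=prefix,
            description=o.description,
            origin=o.origin,
        )
        for o in objects
    ]


def is_clique(members, objects, epsilon):
    by_id = {o.id: o for o in objects}
    return all(
        l2(by_id[a], by_id[b]) <= epsilon + 1e-12 for a, b in combinations(members, 2)
    )


def is_maximal(members, objects, epsilon):
    by_id = {o.id: o for o in objects}
    inside = set(members)
    for o in objects:
        if o.id in inside:
            continue
        if all(l2(o, by_id[m]) <= epsilon + 1e-12 for m in inside):
            return False
    return True
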
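"""Perceptual systems and the perceptual tolerance relation.

A *perceptual object* is a sample (for images, a square subimage) described
by a vector of ``l`` probe-function values, each normalized to ``[0, 1]``.
A *perceptual system* is a finite set of such objects together with the
ordered list of probe names.  Two objects are *tolerance related* at
tolerance ``epsilon`` when the Euclidean distance between their
descriptions is at most ``epsilon``; the relation is reflexive and
symmetric but not transitive.  The *neighbourhood* of an object collects
every object of a pool within ``epsilon`` of it.

These primitives are the substrate for tolerance-class enumeration
(:mod:`nearsets.classes`) and the tNM/tHD resemblance measures
(:mod:`nearsets.measures`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BOUNDARY_SLACK",
    "PerceptualObject",
    "PerceptualSystem",
    "Neighbourhood",
    "tolerance_related",
    "neighbourhood",
    "description_matrix",
]

#: Absolute slack added to the ``<= epsilon`` comparison so that
#: reflexivity survives floating-point round-off.
BOUNDARY_SLACK = 1e-12


@dataclass(frozen=True)
class PerceptualObject:
    """One sample with an ``l``-dimensional normalized description.

    Parameters
    ----------
    id :
        Opaque identifier, unique within a perceptual system.
    set_label :
        Which source set the object belongs to (``"X"``, ``"Y"``, an
        image id, a cluster label, ...).
    description :
        Probe-function values, each in ``[0, 1]``.
    origin :
        Optional ``(column, row)`` grid coordinate of the subimage the
        object came from, so class memberships can be painted back onto
        the image.
    """

    id: str
    set_label: str
    description: tuple[float, ...]
    origin: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        desc = tuple(float(v) for v in self.description)
        object.__setattr__(self, "description", desc)
        if len(desc) == 0:
            raise ValueError(f"object {self.id!r}: empty description")
        for v in desc:
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"object {self.id!r}: feature value {v} outside [0, 1]; "
                    "features must be pre-normalized"
                )

    @property
    def l(self) -> int:
        return len(self.description)


@dataclass
class PerceptualSystem:
    """A finite set of perceptual objects plus their probe names."""

    objects: list[PerceptualObject]
    probe_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.objects:
            raise ValueError("a perceptual system needs a non-empty object set")
        lengths = {o.l for o in self.objects}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent description lengths: {sorted(lengths)}")
        l = lengths.pop()
        if not self.probe_names:
            self.probe_names = [f"f{i + 1}" for i in range(l)]
        if len(self.probe_names) != l:
            raise ValueError(
                f"{len(self.probe_names)} probe names for descriptions of length {l}"
            )
        ids = [o.id for o in self.objects]
        if len(set(ids)) != len(ids):
            raise ValueError("object ids must be unique within a perceptual system")

    @property
    def l(self) -> int:
        return len(self.probe_names)

    def __len__(self) -> int:
        return len(self.objects)

    def __iter__(self):
        return iter(self.objects)

    # ------------------------------------------------------------------
    # serialization: CSV feature tables and JSON round-trip
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.objects:
            row = {"id": o.id, "set_label": o.set_label}
            row.update(dict(zip(self.probe_names, o.description)))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PerceptualSystem":
        feature_cols = [c for c in frame.columns if c not in ("id", "set_label")]
        if not feature_cols:
            raise ValueError("feature table has no feature columns")
        objects = [
            PerceptualObject(
                id=str(row["id"]),
                set_label=str(row["set_label"]),
                description=tuple(float(row[c]) for c in feature_cols),
            )
            for _, row in frame.iterrows()
        ]
        return cls(objects=objects, probe_names=list(feature_cols))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PerceptualSystem":
        return cls.from_frame(pd.read_csv(path))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "probe_names": self.probe_names,
            "objects": [
                {
                    "id": o.id,
                    "set_label": o.set_label,
                    "description": list(o.description),
                    "origin": list(o.origin) if o.origin is not None else None,
                }
                for o in self.objects
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PerceptualSystem":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json")):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        objects = [
            PerceptualObject(
                id=o["id"],
                set_label=o["set_label"],
                description=tuple(o["description"]),
                origin=tuple(o["origin"]) if o.get("origin") is not None else None,
            )
            for o in payload["objects"]
        ]
        return cls(objects=objects, probe_names=list(payload["probe_names"]))


@dataclass(frozen=True)
class Neighbourhood:
    """All objects of a pool within ``epsilon`` of an anchor (anchor included)."""

    anchor_id: str
    member_ids: frozenset[str]
    epsilon: float

    def __contains__(self, object_id: str) -> bool:
        return object_id in self.member_ids

    def __len__(self) -> int:
        return len(self.member_ids)


def description_matrix(objects: Sequence[PerceptualObject]) -> tuple[list[str], np.ndarray]:
    """Stack object descriptions into an ``(n, l)`` array, preserving order."""
    ids = [o.id for o in objects]
    if not ids:
        return ids, np.empty((0, 0))
    mat = np.asarray([o.description for o in objects], dtype=float)
    return ids, mat


def tolerance_related(a: PerceptualObject, b: PerceptualObject, epsilon: float) -> bool:
    """Perceptual tolerance relation: L2 distance of descriptions ``<= epsilon``.

    Reflexive and symmetric; `epsilon` must be non-negative.  The
    comparison carries an absolute slack of :data:`BOUNDARY_SLACK` so the
    boundary case and reflexivity are robust to round-off.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    if a.l != b.l:
        raise ValueError(f"description lengths differ: {a.l} vs {b.l}")
    d = float(np.linalg.norm(np.asarray(a.description) - np.asarray(b.description)))
    return d <= epsilon + BOUNDARY_SLACK


def neighbourhood(
    anchor: PerceptualObject,
    pool: Iterable[PerceptualObject],
    epsilon: float,
) -> Neighbourhood:
    """Neighbourhood of `anchor` within `pool` at tolerance `epsilon`.

    The anchor must itself belong to the pool (by id); it is always a
    member of the result, since the relation is reflexive.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be non-negative, got {epsilon}")
    pool = list(pool)
    ids, mat = description_matrix(pool)
    if anchor.id not in ids:
        raise ValueError(f"anchor {anchor.id!r} is not part of the pool")
    if mat.shape[1] != anchor.l:
        raise ValueError("pool description length differs from anchor's")
    dist = np.linalg.norm(mat - np.asarray(anchor.description), axis=1)
    members = frozenset(i for i, d in zip(ids, dist) if d <= epsilon + BOUNDARY_SLACK)
    return Neighbourhood(anchor_id=anchor.id, member_ids=members, epsilon=float(epsilon))
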
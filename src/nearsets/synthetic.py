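"""Seeded synthetic fixtures: labelled point clouds and oriented-texture
image databases with known ground truth.

The texture generator emulates the statistical structure of a small
retrieval database whose categories differ in edge-orientation
statistics: each category renders anti-aliased sinusoidal gratings
whose normal directions are drawn from a small per-category angle set,
with per-image random phase and additive Gaussian intensity noise.
Smooth gratings keep the gradient orientation well defined everywhere,
so the edge-orientation probe recovers the stripe normal.

All randomness flows through :func:`numpy.random.default_rng` seeded
from the spec, so regeneration under a fixed seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .perceptual import PerceptualObject

__all__ = [
    "CloudSpec",
    "TextureCategory",
    "TextureDatabaseSpec",
    "TextureImage",
    "gen_cloud",
    "gen_texture_db",
    "default_texture_spec",
    "write_texture_db",
]


@dataclass(frozen=True)
class CloudSpec:
    """Specification of a clustered point cloud in ``[0, 1]^l``."""

    n: int
    l: int = 2
    k: int = 2
    centers: tuple[tuple[float, ...], ...] | None = None
    std: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.l < 1 or self.k < 1:
            raise ValueError("n, l and k must all be positive")
        if self.k > self.n:
            raise ValueError(f"more clusters ({self.k}) than objects ({self.n})")
        if self.std < 0:
            raise ValueError("within-cluster std must be non-negative")
        if self.centers is not None:
            if len(self.centers) != self.k:
                raise ValueError(f"{len(self.centers)} centers for k={self.k}")
            for c in self.centers:
                if len(c) != self.l:
                    raise ValueError("center dimensionality differs from l")
                if not all(0.0 <= v <= 1.0 for v in c):
                    raise ValueError("cluster centers must lie in [0, 1]^l")


def gen_cloud(spec: CloudSpec) -> list[PerceptualObject]:
    """Generate ``spec.n`` objects around ``spec.k`` cluster centers.

    Objects are assigned to clusters round-robin; features are the
    center plus isotropic Gaussian noise, clipped to ``[0, 1]``.
    ``set_label`` carries the ground-truth cluster.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.centers is None:
        # keep centers away from the walls so clipping is rare
        centers = rng.uniform(0.1, 0.9, size=(spec.k, spec.l))
    else:
        centers = np.asarray(spec.centers, dtype=float)
    assign = np.arange(spec.n) % spec.k
    noise = rng.normal(0.0, spec.std, size=(spec.n, spec.l)) if spec.std > 0 else 0.0
    feats = np.clip(centers[assign] + noise, 0.0, 1.0)
    return [
        PerceptualObject(
            id=f"p{i:04d}",
            set_label=f"cluster{assign[i]}",
            description=tuple(feats[i]),
        )
        for i in range(spec.n)
    ]


@dataclass(frozen=True)
class TextureCategory:
    """One retrieval category: gratings with normals from `angles_deg`."""

    name: str
    angles_deg: tuple[float, ...]
    period: float = 8.0
    contrast: float = 1.0


@dataclass(frozen=True)
class TextureDatabaseSpec:
    """A small image database of oriented-texture categories."""

    categories: tuple[TextureCategory, ...]
    images_per_category: int = 10
    image_size: tuple[int, int] = (100, 100)
    noise_std: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("at least one texture category is required")
        if self.images_per_category < 1:
            raise ValueError("images_per_category must be positive")
        if min(self.image_size) < 8:
            raise ValueError("image sides must be at least 8 pixels")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


@dataclass(frozen=True)
class TextureImage:
    """A generated grating with its ground-truth normal angle."""

    image_id: str
    category: str
    pixels: np.ndarray  # (M, N) float in [0, 1]
    angle_deg: float  # stripe-normal (gradient) direction


def default_texture_spec(seed: int = 0) -> TextureDatabaseSpec:
    """The stock three-category database used throughout the test-bench.

    Category normals sit at 30°, 90° and 150° — maximally separated on
    the axial circle and interior to the ``[0, π)`` fold interval, so
    the arithmetic folded orientation probe is far from its wrap-around
    discontinuity.  Small per-image angle jitter (±5°) and intensity
    noise provide within-category variation.
    """
    def cat(name: str, center: float) -> TextureCategory:
        return TextureCategory(
            name=name, angles_deg=(center - 5.0, center, center + 5.0)
        )

    return TextureDatabaseSpec(
        categories=(cat("A", 30.0), cat("B", 90.0), cat("C", 150.0)),
        images_per_category=10,
        image_size=(100, 100),
        noise_std=0.02,
        seed=seed,
    )


def grating(
    shape: tuple[int, int],
    angle_deg: float,
    period: float,
    contrast: float = 1.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Anti-aliased sinusoidal grating with normal direction `angle_deg`.

    Intensity ``0.5 + 0.5·contrast·sin(2π u / period + phase)`` where
    ``u`` is the coordinate along the normal; the gradient therefore
    points at ``angle_deg`` (mod π).
    """
    m, n = shape
    alpha = np.deg2rad(angle_deg)
    rows, cols = np.mgrid[0:m, 0:n]
    u = cols * np.cos(alpha) + rows * np.sin(alpha)
    return 0.5 + 0.5 * contrast * np.sin(2 * np.pi * u / period + phase)


def gen_texture_db(spec: TextureDatabaseSpec) -> list[TextureImage]:
    """Render the database; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    images: list[TextureImage] = []
    for cat in spec.categories:
        for i in range(spec.images_per_category):
            angle = float(rng.choice(cat.angles_deg))
            phase = float(rng.uniform(0.0, 2 * np.pi))
            pix = grating(spec.image_size, angle, cat.period, cat.contrast, phase)
            if spec.noise_std > 0:
                pix = pix + rng.normal(0.0, spec.noise_std, size=spec.image_size)
            images.append(
                TextureImage(
                    image_id=f"{cat.name}{i:02d}",
                    category=cat.name,
                    pixels=np.clip(pix, 0.0, 1.0),
                    angle_deg=angle,
                )
            )
    return images


def write_texture_db(
    images: Sequence[TextureImage], out_dir: str | Path
) -> Path:
    """Write PNGs plus a ``labels.csv`` (image_id, category); returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        Image.fromarray((im.pixels * 255).astype(np.uint8), mode="L").save(
            out / f"{im.image_id}.png"
        )
        rows.append({"image_id": im.image_id, "category": im.category})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    return out
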
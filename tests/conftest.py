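import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from nearsets import (
    CloudSpec,
    default_texture_spec,
    gen_cloud,
    gen_texture_db,
    image_to_objects,
)


@pytest.fixture(scope="session")
def texture_db():
    """The stock seeded 3-category oriented-texture database, featurized.

    Returns (database mapping, category labels, raw generated images).
    """
    spec = default_texture_spec(seed=0)
    images = gen_texture_db(spec)
    db = {
        im.image_id: image_to_objects(im.pixels, image_id=im.image_id)
        for im in images
    }
    labels = {im.image_id: im.category for im in images}
    return db, labels, images


@pytest.fixture
def small_cloud():
    """Two well-separated 2-D clusters, 21 objects."""
    return gen_cloud(
        CloudSpec(
            n=21,
            l=2,
            k=2,
            centers=((0.25, 0.25), (0.75, 0.75)),
            std=0.04,
            seed=11,
        )
    )
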
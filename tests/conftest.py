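import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mosaicount as mc

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """A rendered synthetic scene spanning several tiles (session-scoped: ~2 s)."""
    spec = mc.SceneSpec(
        mosaic_id="small", width=2000, height=1400, gsd_cm=2.4,
        n_adult=25, n_calf=8, n_ghost=5, n_rock=5, n_bird=3, n_trunk=3,
        min_separation_px=60, seed=3,
    )
    return spec, mc.generate_scene(spec)


@pytest.fixture(scope="session")
def easy_scene():
    """High-contrast adults only, sparse, no ghosts or distractors."""
    spec = mc.SceneSpec(
        mosaic_id="easy", width=2400, height=1800, gsd_cm=2.4,
        n_adult=40, n_calf=0, n_ghost=0, n_rock=0, n_bird=0, n_trunk=0,
        min_separation_px=90, seed=11,
    )
    return spec, mc.generate_scene(spec)


def make_set(boxes, labels=None, mosaic_id="m1", source_id="src", confs=None):
    """Terse AnnotationSet builder used across test modules."""
    labels = labels or ["adult"] * len(boxes)
    confs = confs or [None] * len(boxes)
    anns = [
        mc.Annotation(mc.BoundingBox(*b), mc.Label(l), c)
        for b, l, c in zip(boxes, labels, confs)
    ]
    return mc.AnnotationSet(mosaic_id, source_id, anns)


@pytest.fixture
def grid_2800():
    return mc.TileGrid("m1", width=2800, height=1000)
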
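import numpy as np
import pytest

from sketchdev import simulate
from sketchdev.corpus import Drawing, Stroke


@pytest.fixture(scope="session")
def small_library():
    return simulate.generate_category_library(8, 4, seed=0)


@pytest.fixture(scope="session")
def age_model():
    return simulate.AgeModel()


def make_drawing(strokes_xy, drawing_id="d0", category="cat", canvas=(100, 100), **kw):
    """Build a Drawing from bare (n, 2) coordinate arrays (timestamps added)."""
    strokes = []
    t = 0.0
    for xy in strokes_xy:
        xy = np.asarray(xy, dtype=float)
        ts = t + 10.0 * np.arange(len(xy))
        t = ts[-1] + 100.0
        strokes.append(Stroke(np.column_stack([xy, ts])))
    defaults = dict(
        drawing_id=drawing_id,
        strokes=tuple(strokes),
        category=category,
        age_years=5,
        session_id=f"sess-{drawing_id}",
        draw_time_s=min(t / 1000.0, 30.0),
        canvas_size=canvas,
    )
    defaults.update(kw)
    return Drawing(**defaults)
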
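"""Shared fixtures: survey constants and small synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from shadowcensus import RasterScene, SceneSpec, generate_scene

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Published survey inputs for the Inexpressible Island colony: shadow-pixel
# totals of the 1983 grayscale and 2012 RGB aerial surveys, the per-bird
# shadow-pixel factor, and the accuracy-sample precision/recall table.
SURVEY_PIXELS = {"1983": 236_253, "2012": 292_323}
P_PER_PENGUIN = 13.8
ACCURACY_SAMPLES = {
    "gray_1983": [
        (0.72, 0.77), (0.79, 0.81), (0.65, 0.70),
        (0.77, 0.78), (0.80, 0.79), (0.76, 0.77),
    ],
    "rgb_2012": [
        (0.74, 0.76), (0.89, 0.75), (0.74, 0.77),
        (0.85, 0.72), (0.74, 0.78), (0.84, 0.82),
    ],
}
# Seasonal budget results of the two population methods (kg gas; kg CO2-eq)
# as tabulated for the two surveys — the fitting-method numbers are treated
# purely as comparison inputs (see docs/methods.md).
TABLE2 = {
    "1983": {"avg": (69.82, 0.76, 5155.98), "fit": (73.82, 0.80, 5449.75)},
    "2012": {"avg": (86.39, 0.94, 6379.63), "fit": (91.34, 0.99, 6743.23)},
}


@pytest.fixture(scope="session")
def dense_scene():
    """A colony-density scene (50 birds on an 8 m crop) with truth."""
    spec = SceneSpec(n_penguins=50, image_size_px=(80, 80), seed=11)
    scene, layout = generate_scene(spec)
    return spec, scene, layout


@pytest.fixture()
def flat_scene():
    return RasterScene(np.full((8, 8), 0.5), resolution_m=0.1)


@pytest.fixture()
def step_scene():
    img = np.full((8, 8), 0.8)
    img[:, :4] = 0.2
    return RasterScene(img, resolution_m=0.1)
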
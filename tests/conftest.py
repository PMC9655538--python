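import numpy as np
import pytest

from rootscreen.plate_core import PlantId, PlateGeometry
from rootscreen.root_pheno import (
    binarize_root_image,
    build_root_graph,
    classify_root_orders,
    measure_traits,
)
from rootscreen.synth_plate import SimParams, render_root_image, simulate_root_system


@pytest.fixture(scope="session")
def geom1():
    """Single-hole plate at the default 4 px/mm calibration."""
    return PlateGeometry(n_holes=1)


@pytest.fixture(scope="session")
def geom3():
    return PlateGeometry()


def analyze_simulated_plant(seed, day, geom, stroke_px=3, noise_sd=0.18,
                            treatment="Amb-Ctl", **sim_kw):
    """Simulate one plant, render, run the full root pipeline.

    Returns (truth, labeled graph, measured traits).
    """
    params = SimParams(rng_seed=seed, **sim_kw)
    truth = simulate_root_system(params, PlantId("t", 0), day, geom, treatment)
    img, _ = render_root_image(truth, geom, stroke_px=stroke_px,
                               noise_sd=noise_sd, rng=seed + 100)
    mask = binarize_root_image(img)
    graph = build_root_graph(mask, geom)
    classify_root_orders(graph)
    return truth, graph, measure_traits(graph, dai=day)
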
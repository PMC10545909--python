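import numpy as np
import pytest

import pulsescope as ps
from pulsescope.synthetic import BackgroundParams, Kinetics, NoiseParams, SceneParams


@pytest.fixture
def standard_timeline() -> ps.ProtocolTimeline:
    """3 dark + 6 actinic + 6 relaxation frames, 60 s apart (15 min run)."""
    return ps.build_timeline(3, 6, 6, 60.0, actinic_intensity=500.0)


@pytest.fixture
def noise_free_scene() -> SceneParams:
    """Default scene geometry with all noise sources disabled."""
    return SceneParams(noise=NoiseParams(poisson=False, gaussian_sd=0.0))


def measure_cell_npq(
    stack: ps.AcquisitionStack,
    truth: ps.GroundTruth,
    timeline: ps.ProtocolTimeline,
    cell: int,
):
    """Project, trace, background-correct and compute NPQ for one cell."""
    series = ps.sum_project(stack)
    bg = ps.mean_gray(series, ps.Roi("bg", truth.background_mask, role="background"))
    tr = ps.mean_gray(series, ps.Roi(f"cell{cell}", truth.cell_footprints[cell]))
    corrected = ps.subtract_background(tr, bg)
    return ps.compute_npq_series(corrected, timeline)
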
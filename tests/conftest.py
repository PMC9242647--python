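"""Shared fixtures: every stack used in tests is generated at run time."""
from __future__ import annotations

import numpy as np
import pytest

from pmindex import default_model, generate_geometry, render_stack, run_pipeline
from pmindex.synthetic import roi_for_cell

DEFAULT_CHANNELS = ("PI4P", "PIP2", "Lgl")


@pytest.fixture(scope="session")
def tissue_geometry():
    return generate_geometry(16, (256, 256), mode="tissue", seed=1)


@pytest.fixture(scope="session")
def default_sim(tissue_geometry):
    """The shipped-default 90-frame, 16-cell hypoxia/reoxygenation movie."""
    model = default_model()
    stack, gt = render_stack(tissue_geometry, model, n_frames=90, seed=2)
    rois = [roi_for_cell(tissue_geometry, lab) for lab in tissue_geometry.labels]
    for roi in rois:
        roi.validate(stack.frame_shape)
    return {"stack": stack, "gt": gt, "rois": rois, "model": model,
            "geometry": tissue_geometry}


@pytest.fixture(scope="session")
def default_series(default_sim):
    """Pipeline output for the default simulation (PM-index channels only)."""
    return run_pipeline(default_sim["stack"], default_sim["rois"],
                        channels=list(DEFAULT_CHANNELS))


@pytest.fixture(scope="session")
def small_sim():
    """A cheap 4-cell, 12-frame movie for unit tests."""
    geometry = generate_geometry(4, (128, 128), mode="tissue", seed=3)
    model = default_model(t_hypoxia=120.0, t_reoxy=480.0)
    stack, gt = render_stack(geometry, model, n_frames=12, frame_interval=60.0,
                             seed=4, keep_noiseless=True)
    rois = [roi_for_cell(geometry, lab) for lab in geometry.labels]
    return {"stack": stack, "gt": gt, "rois": rois, "model": model,
            "geometry": geometry}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
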
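"""Shared fixtures: the default synthetic study, rendered once per session."""

import numpy as np
import pytest

from cocoahsi.hypercube import calibrate_reflectance, exclude_bands
from cocoahsi.pls import run_calibration
from cocoahsi.synthetic import (SceneParams, StudyDesign, default_endmembers,
                                generate_study, render_scan, sample_beans)


@pytest.fixture(scope="session")
def design():
    return StudyDesign(seed=1)


@pytest.fixture(scope="session")
def scene():
    return SceneParams()


@pytest.fixture(scope="session")
def endmembers(scene):
    return default_endmembers(scene.wavelengths)


@pytest.fixture(scope="session")
def truth(design):
    return sample_beans(design)


@pytest.fixture(scope="session")
def shelled_table(design, scene, truth):
    _, table, _ = generate_study(design, scene, truth=truth, keep_scans=False)
    return table


@pytest.fixture(scope="session")
def inshell_table(design, scene, truth):
    in_design = StudyDesign(seed=design.seed, presentation="in_shell")
    _, table, _ = generate_study(in_design, scene, truth=truth, keep_scans=False)
    return table


@pytest.fixture(scope="session")
def snv_model(shelled_table):
    model, report, _ = run_calibration(shelled_table, "snv", seed=42)
    return model, report


@pytest.fixture(scope="session")
def noise_free_study():
    """Noise-free, scatter-free study plus one calibrated scan of batch 2."""
    design0 = StudyDesign(seed=3, reference_noise_sd=0.0, moisture_noise_sd=0.0)
    truth0 = sample_beans(design0)
    scene0 = SceneParams().noise_free()
    _, table0, _ = generate_study(design0, scene0, truth=truth0, keep_scans=False)
    model0, _, _ = run_calibration(table0, "log1r", seed=42)
    endm = default_endmembers(scene0.wavelengths)
    raw, refs, scene_truth = render_scan(truth0, endm, scene0, batch=2, side=1)
    cube = exclude_bands(calibrate_reflectance(raw, refs), scene0.n_junk_bands)
    return {"design": design0, "truth": truth0, "scene": scene0,
            "table": table0, "model": model0, "cube": cube,
            "scene_truth": scene_truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
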
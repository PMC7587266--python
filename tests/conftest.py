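"""Shared fixtures: small-geometry synthetic scenes and pipeline runs.

Scenes are rendered at reduced lateral/axial sampling (512 A-scans,
320 depth pixels, few repeats) so the whole suite stays fast; the scene
content (layer depths, birefringence levels, vessels) matches the
full-size protocol.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from psoct_rnfl.synthetic_data import (NoiseParams, ScanGeometry,
                                       make_phantom,
                                       render_circular_sequence)
from psoct_rnfl.workbench import PipelineConfig, run_subject


def small_geometry(n_bscans: int = 4, n_ascans: int = 512,
                   n_depth: int = 320) -> ScanGeometry:
    return ScanGeometry(n_ascans_per_bscan=n_ascans, n_bscans=n_bscans,
                        n_depth_pixels=n_depth)


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseParams:
    return NoiseParams.quiet()


@pytest.fixture(scope="session")
def flat_quiet_scene(quiet_noise):
    """Noise-free constant scene: 125 um thickness, 0.135 deg/um."""
    geometry = small_geometry(n_bscans=4)
    phantom = make_phantom("flat", {"noise": quiet_noise}, seed=0, n_phi=512)
    pairs, gt = render_circular_sequence(phantom, geometry, seed=1)
    return phantom, geometry, pairs, gt


@pytest.fixture(scope="session")
def flat_quiet_run(flat_quiet_scene):
    phantom, geometry, pairs, gt = flat_quiet_scene
    config = PipelineConfig(geometry=geometry, noise=phantom.noise,
                            n_select=len(pairs))
    avg, seg, profile, summary = run_subject(pairs, config, "flat")
    return dict(phantom=phantom, geometry=geometry, pairs=pairs, gt=gt,
                config=config, avg=avg, seg=seg, profile=profile,
                summary=summary)


@pytest.fixture(scope="session")
def healthy_quiet_run(quiet_noise):
    """Noise-free double-hump scene with vessels, through the pipeline.

    Full 2048-A-scan lateral sampling: vessel-mask dilation is defined in
    A-scan units, so false-positive rates are only meaningful at the
    protocol's native sampling.
    """
    geometry = small_geometry(n_bscans=2, n_ascans=2048)
    phantom = make_phantom("healthy", {"noise": quiet_noise}, seed=2)
    pairs, gt = render_circular_sequence(phantom, geometry, seed=3)
    config = PipelineConfig(geometry=geometry, noise=quiet_noise, n_select=2)
    avg, seg, profile, summary = run_subject(pairs, config, "healthy-quiet")
    return dict(phantom=phantom, geometry=geometry, pairs=pairs, gt=gt,
                config=config, avg=avg, seg=seg, profile=profile,
                summary=summary)


@pytest.fixture(scope="session")
def healthy_noisy_run():
    """Default-noise healthy scene, 16 repeats, 12 selected."""
    geometry = small_geometry(n_bscans=16)
    phantom = make_phantom("healthy", seed=7, n_phi=512)
    pairs, gt = render_circular_sequence(phantom, geometry, seed=107)
    config = PipelineConfig(geometry=geometry, noise=phantom.noise,
                            n_select=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        avg, seg, profile, summary = run_subject(pairs, config, "healthy")
    return dict(phantom=phantom, geometry=geometry, pairs=pairs, gt=gt,
                config=config, avg=avg, seg=seg, profile=profile,
                summary=summary)


def reference_axial_shift(run: dict) -> int:
    """Global axial offset of the averaged tomogram relative to the
    unjittered ground truth (the reference frame's own rendered shift)."""
    ref = run["avg"].reference_index
    return int(run["gt"].shifts[ref, 0]) if ref >= 0 else 0
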
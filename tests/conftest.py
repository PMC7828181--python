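"""Shared fixtures; the expensive denoising artifacts are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import veinforge as vf


@pytest.fixture(scope="session")
def phantom128():
    """Small bright-vessel phantom with L=4 speckle for unit tests."""
    spec = vf.default_phantom_spec(128, 128, seed=0, polarity="bright")
    clean, truth, fov = vf.generate_phantom(spec)
    noisy = np.clip(vf.apply_speckle(clean, vf.NoiseSpec(looks=4.0, seed=0)), 0, 1)
    return {"clean": clean, "truth": truth, "fov": fov, "noisy": noisy}


@pytest.fixture(scope="session")
def phantom256_l4():
    """The 256x256 fixed-seed L=4 phantom used for denoising efficacy checks."""
    spec = vf.default_phantom_spec(256, 256, seed=0, polarity="bright")
    clean, truth, fov = vf.generate_phantom(spec)
    noisy = np.clip(vf.apply_speckle(clean, vf.NoiseSpec(looks=4.0, seed=0)), 0, 1)
    return {"clean": clean, "truth": truth, "fov": fov, "noisy": noisy}


@pytest.fixture(scope="session")
def esbm3d_l4(phantom256_l4):
    """Ensemble + per-member denoised outputs of the L=4 phantom (expensive)."""
    cfg = vf.default_ensemble(looks=4.0)
    combined, members = vf.ensemble_denoise(phantom256_l4["noisy"], cfg,
                                            return_members=True)
    return {"ensemble": combined, "members": members, "cfg": cfg}


@pytest.fixture(scope="session")
def pipeline_l8():
    """Default-config segmentations of the fixed-seed dark phantom at L=8."""
    spec = vf.default_phantom_spec(256, 256, seed=0, polarity="dark")
    clean, truth, fov = vf.generate_phantom(spec)
    noisy = np.clip(vf.apply_speckle(clean, vf.NoiseSpec(looks=8.0, seed=0)), 0, 1)
    out = {"truth": truth, "fov": fov}
    for det in ("frangi", "multiscale"):
        mask, vmap, log = vf.segment(noisy, fov, vf.PipelineConfig(detector=det))
        out[det] = {"mask": mask, "vmap": vmap, "log": log}
    return out


@pytest.fixture(scope="session")
def pipeline_l4_denoise_vs_bypass():
    """Dark phantom at L=4 segmented with and without the ES-BM3D stage."""
    spec = vf.default_phantom_spec(256, 256, seed=0, polarity="dark")
    clean, truth, fov = vf.generate_phantom(spec)
    noisy = np.clip(vf.apply_speckle(clean, vf.NoiseSpec(looks=4.0, seed=0)), 0, 1)
    out = {"truth": truth, "fov": fov}
    for det in ("frangi", "multiscale"):
        mask_on, _, _ = vf.segment(noisy, fov, vf.PipelineConfig(detector=det))
        mask_off, _, _ = vf.segment(noisy, fov,
                                    vf.PipelineConfig(detector=det, denoise=False))
        out[det] = {"denoise": mask_on, "bypass": mask_off}
    return out
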
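"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

import kernelct as kc


def make_segmenter(spec: kc.KernelPhantomSpec, **overrides) -> kc.KernelSegmenter:
    """Segmenter in phantom test mode: midpoint thresholds at the known greys."""
    kwargs = dict(
        threshold_method="midpoint",
        grey_levels=dict(spec.grey_levels),
        coat_thickness_mm=spec.coat_thickness_mm,
    )
    kwargs.update(overrides)
    return kc.KernelSegmenter(**kwargs)


@pytest.fixture(scope="session")
def clean_phantom():
    """Default kernel phantom without noise, with its ground truth."""
    spec = kc.KernelPhantomSpec(noise_sd=0.0, rng_seed=1)
    volume, truth = kc.generate_kernel_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same kernel geometry with 8-grey-level Gaussian noise."""
    spec = kc.KernelPhantomSpec(noise_sd=8.0, rng_seed=1)
    volume, truth = kc.generate_kernel_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def sphere_phantom():
    """Voxelized 4-mm-radius sphere at 50 um voxels (analytic oracle)."""
    spec = kc.KernelPhantomSpec(
        body_semi_axes_mm=(4.0, 4.0, 4.0),
        shape_exponent=2.0,
        voxel_size_um=50.0,
        embryo_fraction=0.0,
        cavity_spec={},
        noise_sd=0.0,
        rng_seed=0,
    )
    volume, truth = kc.generate_kernel_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def variety_table():
    return kc.datasets.load_variety_means()


@pytest.fixture(scope="session")
def coarse_template():
    """Small phantom spec for fast end-to-end runs (150 um voxels)."""
    return kc.KernelPhantomSpec(
        voxel_size_um=150.0,
        cavity_spec={
            "subcutaneous": kc.phantom.CavityClassSpec(2, (0.45, 0.6)),
            "endosperm": kc.phantom.CavityClassSpec(2, (0.5, 0.7)),
            "embryo": kc.phantom.CavityClassSpec(1, (0.35, 0.45)),
        },
    )
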
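"""Shared fixtures: small analytic grids and session-scoped phantoms.

The full-size head phantom is expensive to build (distance transforms on
a ~3M-voxel grid), so the anatomy is constructed once per session via
:class:`PhantomFactory` and only noise is resampled where tests sweep
seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from sonoquant.synthetic import EnhancementSpec, PhantomFactory, PhantomSpec


def make_grid(shape=(20, 20, 20), spacing=1.0):
    """A centered 1-mm (by default) grid: world origin at the volume center."""
    from sonoquant.volumes import VolumeGrid

    shape = np.asarray(shape, int)
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    affine[:3, 3] = -spacing * (shape - 1) / 2.0
    return VolumeGrid(np.zeros(tuple(shape)), affine, frame="test")


def small_spec(**kw):
    """A reduced head that keeps unit tests fast; the enhancement cylinder
    is shrunk with it so the geometry stays valid."""
    enh = kw.pop(
        "enhancement", EnhancementSpec(length_mm=6.0, diameter_mm=6.0, offset_mm=10.0)
    )
    return PhantomSpec(
        shape=(64, 64, 64),
        semi_axes_mm=(28.0, 30.0, 26.0),
        enhancement=enh,
        **kw,
    )


@pytest.fixture(scope="session")
def small_labels():
    from sonoquant.synthetic import make_labels

    return make_labels(small_spec())[0]


@pytest.fixture(scope="session")
def clean_factory() -> PhantomFactory:
    """Noise-free default phantom anatomy (planted 0.2 mM enhancement)."""
    return PhantomFactory(PhantomSpec(t1_noise_sd_s=0.0))


@pytest.fixture(scope="session")
def noisy_factory() -> PhantomFactory:
    """Default phantom anatomy at the default T1 noise (0.02 s)."""
    return PhantomFactory(PhantomSpec())


@pytest.fixture(scope="session")
def null_factory() -> PhantomFactory:
    """No planted enhancement, default noise: the detection null condition."""
    return PhantomFactory(PhantomSpec(enhancement=EnhancementSpec(c_true_mm=0.0)))


@pytest.fixture(scope="session")
def clean_phantom(clean_factory):
    return clean_factory.sample(0)


@pytest.fixture(scope="session")
def beam_and_control(clean_phantom):
    from sonoquant import cylinder_mask, mirror_mask

    beam = cylinder_mask(clean_phantom.geometry, clean_phantom.pre)
    control = mirror_mask(beam, clean_phantom.pre)
    control.name = "control"
    return beam, control
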
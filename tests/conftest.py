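import numpy as np
import pytest

from aaastrain import MotionGrid, PhantomSpec, generate_phantom


def cylinder_grid(
    radius=10.0,
    length=40.0,
    n=6,
    m=36,
    frames=(1.0, 1.0),
    axial=None,
    axis="z",
):
    """Analytic cylinder motion grid; per-frame radial and axial scale factors."""
    if axial is None:
        axial = (1.0,) * len(frames)
    x = np.linspace(0.0, length, n)
    phi = 2 * np.pi * np.arange(m) / m - np.pi
    X, PHI = np.meshgrid(x, phi, indexing="ij")
    pos = []
    for rs, zs in zip(frames, axial):
        R = radius * rs
        p = np.stack([R * np.cos(PHI), R * np.sin(PHI), X * zs], axis=-1)
        pos.append(p)
    pos = np.stack(pos, axis=0)
    if axis == "x":
        pos = pos[..., [2, 0, 1]]
    return MotionGrid(pos, patient_id="test", segmentation_id="cyl")


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced phantom for fast end-to-end tests."""
    return PhantomSpec(n_heights=10, n_frames=8, length=50.0)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return generate_phantom(small_spec)
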
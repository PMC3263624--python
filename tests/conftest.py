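import numpy as np
import pytest

from brainshift_xfem.core_mesh import LabelImage3D, tetrahedralize_labeled_grid


def make_sphere_labels(n=48, spacing=1.0, brain_r=20.0, tumor_r=8.0):
    idx = np.indices((n, n, n)).astype(float)
    c = (n - 1) / 2.0
    r = np.sqrt(((idx - c) ** 2).sum(axis=0)) * spacing
    lab = np.zeros((n, n, n), dtype=np.int32)
    lab[r < brain_r] = 1
    lab[r < tumor_r] = 2
    return LabelImage3D(lab, spacing=(spacing,) * 3)


def make_bar_mesh(nx=9, ny=5, nz=5, pitch=0.25):
    """Structured all-healthy bar mesh spanning [0, (nx-1)*pitch] x ..."""
    lab = LabelImage3D(np.ones((nx, ny, nz), dtype=np.int32), spacing=(pitch,) * 3)
    return tetrahedralize_labeled_grid(lab, pitch)


@pytest.fixture(scope="session")
def sphere_labels():
    return make_sphere_labels()


@pytest.fixture(scope="session")
def sphere_mesh(sphere_labels):
    return tetrahedralize_labeled_grid(sphere_labels, 5.0)


@pytest.fixture(scope="session")
def bar_mesh():
    return make_bar_mesh()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
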
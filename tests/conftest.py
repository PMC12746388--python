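import numpy as np
import pytest

from mcgre import (
    DEFAULT_TISSUES,
    SequenceParams,
    make_background_phase,
    make_coil_maps,
    make_phantom,
    synthesize_ideal_images,
)


@pytest.fixture(scope="session")
def default_seq() -> SequenceParams:
    return SequenceParams()  # TR 5.5 ms, TE (0.08, 2.38) ms, flip 24, theta 1.5


@pytest.fixture(scope="session")
def brain_tissues():
    return [DEFAULT_TISSUES[k] for k in ("wm", "gm", "csf")]


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom((48, 48), seed=7)


@pytest.fixture(scope="session")
def ideal_images(small_phantom, default_seq):
    phase = make_background_phase((48, 48), np.pi / 3, seed=8)
    return synthesize_ideal_images(small_phantom, default_seq, phase), phase


@pytest.fixture(scope="session")
def coils48():
    return make_coil_maps((48, 48), 4, seed=9)


def direct_ndft(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Brute-force oracle for the unitary centered (N)DFT convention."""
    grid = image.shape
    axes = [np.arange(n) - n // 2 for n in grid]
    mesh = np.meshgrid(*axes, indexing="ij")
    x = np.stack([m.ravel() for m in mesh], axis=-1)
    phases = np.exp(-2j * np.pi * (coords @ x.T))
    return phases @ image.ravel() / np.sqrt(np.prod(grid))
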
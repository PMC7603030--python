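import numpy as np
import pytest

from secrflux import simulate
from secrflux.stack import CellROI, ImageStack


def split_channels(stack: ImageStack) -> tuple[ImageStack, ImageStack]:
    """(cargo, marker) single-channel stacks from a two-channel series."""
    cargo = ImageStack(
        data=stack.data[:, 0][:, None], timepoints_min=stack.timepoints_min
    )
    marker = ImageStack(
        data=stack.data[:, 1][:, None], timepoints_min=stack.timepoints_min
    )
    return cargo, marker


@pytest.fixture(scope="session")
def transport_series():
    """One noise-free single-cell transport series with strong kinetics,
    shared across tests (read-only)."""
    scene = simulate.SceneParams(
        image_shape=(192, 192), golgi_radius_px=20, seed=11, background_level=5.0
    )
    kinetics = simulate.TransportKinetics(
        golgi_fraction=(0.05, 0.2, 0.4, 0.6, 0.9)
    )
    stack, truth = simulate.generate_transport_series(scene, kinetics)
    roi = CellROI(1, truth.cell_masks_true == 1, source="ground_truth")
    return stack, truth, roi, kinetics


@pytest.fixture(scope="session")
def vesicle_movie_directed():
    params = simulate.VesicleMovieParams(
        n_frames=80, n_vesicles=10, speed_px_per_frame=1.5, motion="directed", seed=7
    )
    return simulate.generate_vesicle_movie(params), params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
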
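import numpy as np
import pytest

from synaptraffick.puncta import ChannelImage
from synaptraffick.scenes import Punctum, SceneTruth, make_dendrite_scene


def well_separated_truth(n_synaptic=5, n_extrasynaptic=5, seed=0,
                         noise_sd=0.0, peak=200.0, sigma_um=0.15,
                         shape=(128, 128)):
    """Puncta on a jittered grid, far enough apart to never merge."""
    rng = np.random.default_rng(seed)
    n = n_synaptic + n_extrasynaptic
    w_um = shape[1] * 0.1
    h_um = shape[0] * 0.1
    side = int(np.ceil(np.sqrt(n)))
    xs = np.linspace(1.5, w_um - 1.5, side)
    ys = np.linspace(1.5, h_um - 1.5, side)
    centres = [(x, y) for y in ys for x in xs][:n]
    puncta = [
        Punctum(x_um=float(x + rng.uniform(-0.3, 0.3)),
                y_um=float(y + rng.uniform(-0.3, 0.3)),
                peak=peak, sigma_um=sigma_um, synaptic=(i < n_synaptic))
        for i, (x, y) in enumerate(centres)
    ]
    return SceneTruth(puncta=puncta, background_level=10.0,
                      gaussian_sd=noise_sd, shape=shape, seed=seed)


@pytest.fixture
def noiseless_scene():
    truth = well_separated_truth()
    images, truth = make_dendrite_scene(truth)
    return images, truth


@pytest.fixture
def flat_image():
    return ChannelImage(pixels=np.full((32, 32), 7.0), pixel_size_um=0.1,
                        channel="flat")
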
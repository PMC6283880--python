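import numpy as np
import pytest

from smtkin.schedules import continuous, interlaced, timelapse
from smtkin.synthetic import TBP_LIKE, SOX19B_LIKE, EmbryoScenario, render_movie


@pytest.fixture
def itm_schedule():
    return interlaced()


@pytest.fixture(scope="session")
def small_movie():
    """A sparse SNR-4 movie with ground truth, shared across tests."""
    scenario = EmbryoScenario("oblong", 200.0, 400, 0.5, 0.2)
    return render_movie(
        scenario, TBP_LIKE, continuous(0.25), snr=4.0, seed=7,
        n_frames=40, shape=(48, 48),
    )


def gaussian_spot(shape, y0, x0, amplitude, sigma_px, background=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma_px**2)
    )
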
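import numpy as np
import pytest

from musical_sr import PSFModel, make_pair_scene, calibrate_brightness
from musical_sr.profiles import local_maxima_1d, sample_line_profile


@pytest.fixture(scope="session")
def psf593():
    """Paper-style optics: NA 1.49 objective, 593 nm emission, 65 nm pixels."""
    return PSFModel("airy", 1.49, 593.0, 65.0)


@pytest.fixture(scope="session")
def psf512():
    return PSFModel("airy", 1.49, 512.0, 65.0)


@pytest.fixture(scope="session")
def pair_scene_50nm(psf593):
    """High-SBR two-point scene at 50 nm separation (sub-pixel)."""
    scene = make_pair_scene(
        50.0, psf593, (15, 15), brightness=100.0, p_on=0.2, background=10.0
    )
    return calibrate_brightness(scene, 10.0)


def pair_peak_errors(map_, scene):
    """Locate the two dominant peaks along the emitter axis of a pair scene.

    Returns (errors_nm, contrast): absolute x-position error of each peak
    against the matching true emitter, and the two-peak dip contrast, or
    (None, 0.0) if fewer than two local maxima are found.
    """
    s = round(scene.psf.pixel_size / map_.pixel_size_out)
    (ey, e1x), (_, e2x) = (e.position for e in scene.emitters)
    row = (ey + 0.5) * s - 0.5
    col0 = (e1x - 2 + 0.5) * s - 0.5
    col1 = (e2x + 2 + 0.5) * s - 0.5
    prof = sample_line_profile(map_, (row, col0), (row, col1), 400)
    peaks = local_maxima_1d(prof.values)
    if len(peaks) < 2:
        return None, 0.0
    top2 = np.sort(peaks[np.argsort(prof.values[peaks])[::-1][:2]])
    pos = prof.positions[top2]
    true_pos = (np.array([e1x, e2x]) - (e1x - 2)) * scene.psf.pixel_size
    errors = np.abs(pos - true_pos)
    p_mean = prof.values[top2].mean()
    dip = prof.values[top2[0] : top2[1] + 1].min()
    contrast = (p_mean - dip) / (p_mean + dip)
    return errors, contrast
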
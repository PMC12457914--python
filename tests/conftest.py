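import numpy as np
import pytest

import hullscape as hs
from hullscape import synthdata


@pytest.fixture(scope="session")
def default_palette():
    return synthdata.default_palette()


@pytest.fixture(scope="session")
def synth_plate():
    """One rendered plate of 30 nuts with its ground-truth manifest."""
    plate, truth = synthdata.make_plate(30, seed=1, canvas=(1500, 2000))
    return plate, truth


@pytest.fixture(scope="session")
def segmented_plate(synth_plate):
    plate, truth = synth_plate
    nuts = hs.segment_plate(hs.white_balance(plate))
    return nuts, truth


@pytest.fixture(scope="session")
def printed_tables():
    return synthdata.fixtures()


def ellipse_ensemble(a=40, b=20, angle=0.0, centre=(60.0, 60.0), protrusion=0.0,
                     protrusion_width=6.0):
    """Pixel ensemble of a filled rotated ellipse with an optional tip spike.

    Returns (ensemble, apex) where apex is the true protrusion tip (or the
    +long-axis ellipse endpoint when protrusion == 0).
    """
    reach = int(a + protrusion + 3)
    xs, ys = np.meshgrid(
        np.arange(int(centre[0]) - reach, int(centre[0]) + reach + 1),
        np.arange(int(centre[1]) - reach, int(centre[1]) + reach + 1),
    )
    dx, dy = xs - centre[0], ys - centre[1]
    c, s = np.cos(angle), np.sin(angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if protrusion > 0:
        lam = (u - a * 0.6) / (a * 0.4 + protrusion)
        half = np.maximum(protrusion_width / 2 * (1 - lam), 1.2)
        mask |= (lam >= 0) & (lam <= 1) & (np.abs(v) <= half)
    coords = np.column_stack([xs[mask], ys[mask]])
    colours = np.full((len(coords), 3), 128, dtype=np.uint8)
    apex = (centre[0] + (a + protrusion) * c, centre[1] + (a + protrusion) * s)
    return hs.PixelEnsemble(coords, colours), apex
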
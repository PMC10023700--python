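"""Shared fixtures: phantoms and registered pairs at two problem sizes.

Unit tests use a 64-voxel-cube phantom; the full-resolution (128-cube,
50 µm) default phantom and its registration are session-scoped so the
expensive stages run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from microvent import (
    demons_register,
    grey_to_hu,
    svg_map,
    ventilation_map,
    warp,
)
from microvent.phantom import Phantom, PhantomSpec, generate_phantom

SMALL_SHAPE = (64, 64, 64)


def hu_pair(ph: Phantom):
    """(inspiratory, expiratory) HU volumes of a phantom."""
    cal = ph.truth.calibration
    return grey_to_hu(ph.insp_raw, cal), grey_to_hu(ph.exp_raw, cal)


def subject_svg_maps(ph: Phantom, field=None):
    """(SVg_insp, warped SVg_exp, dSVg) for a phantom; truth field by default."""
    hu_i, hu_e = hu_pair(ph)
    fld = ph.truth.field if field is None else field
    warped = warp(hu_e, fld)
    svg_i = svg_map(hu_i, ph.mask_insp)
    svg_e = svg_map(warped, ph.mask_insp)
    return svg_i, svg_e, ventilation_map(svg_i, svg_e, ph.mask_insp)


def saline_pools(phantoms):
    """Pooled (SVg_insp, SVg_exp, dSVg) in-mask sample lists for a cohort."""
    pools = ([], [], [])
    for ph in phantoms:
        svg_i, svg_e, dsvg = subject_svg_maps(ph)
        m = ph.mask_insp.data
        pools[0].append(svg_i.data[m])
        pools[1].append(svg_e.data[m])
        pools[2].append(dsvg.data[m])
    return pools


@pytest.fixture(scope="session")
def small_phantom() -> Phantom:
    return generate_phantom(PhantomSpec(shape=SMALL_SHAPE, seed=3))


@pytest.fixture(scope="session")
def default_phantom() -> Phantom:
    """The default noise-free phantom: 128 cube, 50 µm, seed 7, 10 landmarks."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_registration(default_phantom):
    """Four-level Demons registration of the default phantom pair."""
    hu_i, hu_e = hu_pair(default_phantom)
    return demons_register(
        hu_i,
        hu_e,
        mask=default_phantom.mask_insp,
        landmarks=default_phantom.truth.landmarks,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
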
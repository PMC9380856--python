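import warnings

import numpy as np
import pytest

import lentimorph as lm


@pytest.fixture(scope="session")
def default_config():
    return lm.published_cohort_defaults()


@pytest.fixture(scope="session")
def tabular_cohort(default_config):
    """Default three-group cohort (n=19 each), tabular mode, fixed seed."""
    groups, noise = default_config
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lm.generate_cohort(groups, noise, mode="tabular", seed=11)


@pytest.fixture(scope="session")
def image_cohort(default_config):
    """Default cohort rendered and measured through the morphometry module."""
    groups, noise = default_config
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lm.generate_cohort(groups, noise, mode="image", seed=11)


@pytest.fixture(scope="session")
def tabular_indices(tabular_cohort):
    return lm.indices_table(tabular_cohort)


def make_phantom_spec(
    a=7.5, b=3.0, x_ref_offset=0.0, noise_sd=0.0, texture_sd=0.0, seed=0,
    spacing=0.5, shape=(96, 96),
):
    """One-LN test scene: identical left/right ellipses, CSF ROI below."""
    width = shape[1] * spacing
    cx_left, cx_right = width * 0.27, width * 0.73
    cy = 18.0
    csf = lm.EllipseRoiSpec(width / 2.0, 38.0, 4.0, 3.0, 700.0, texture_sd)
    return lm.PhantomSpec(
        image_shape=shape,
        pixel_spacing=spacing,
        left_ln=lm.EllipseRoiSpec(cx_left, cy, a, b, 300.0, texture_sd),
        right_ln=lm.EllipseRoiSpec(cx_right, cy, a, b, 300.0, texture_sd),
        csf_roi=csf,
        background_intensity=400.0,
        noise_sd=noise_sd,
        x_ref_left=cx_left + x_ref_offset,
        x_ref_right=cx_right + x_ref_offset,
        seed=seed,
    )


def random_blob_mask(rng, shape=(40, 40)):
    """Random connected blob: union of a few filled discs."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = np.zeros(shape, dtype=bool)
    cy, cx = rng.integers(8, rows - 8), rng.integers(8, cols - 8)
    for _ in range(rng.integers(1, 5)):
        r = rng.integers(2, 7)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        cy = int(np.clip(cy + rng.integers(-4, 5), 4, rows - 5))
        cx = int(np.clip(cx + rng.integers(-4, 5), 4, cols - 5))
    return mask
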
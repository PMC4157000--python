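import numpy as np
import pytest

from cimt.image_io import DEFAULT_PIXEL_DENSITY, GrayImage
from cimt.roi import build_template
from cimt.synthetic import PhantomSpec, generate_phantom


def gray(arr, density: float = DEFAULT_PIXEL_DENSITY) -> GrayImage:
    """Wrap a plain array as a GrayImage."""
    return GrayImage(np.asarray(arr, dtype=float), density)


@pytest.fixture(scope="session")
def clean_phantom():
    """A noiseless default phantom with its ground-truth boundaries."""
    return generate_phantom(PhantomSpec(imt_mm=0.7))


@pytest.fixture(scope="session")
def template(clean_phantom):
    """A 21x15 matching template cut at the IMC center of the clean phantom."""
    img, gt_lii, gt_mai = clean_phantom
    center_row = int(round((gt_lii.rows[0] + gt_mai.rows[0]) / 2))
    return build_template(img, (center_row, img.n_cols // 2), (21, 15))
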
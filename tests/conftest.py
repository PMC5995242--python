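import numpy as np
import pytest

from lymphmorph import synthetic as syn
from lymphmorph import segmentation as seg


@pytest.fixture(scope="session")
def rendered_core():
    """One rendered synthetic TMA core with 20% open-walled vessels."""
    vessels = syn.sample_core_vessels(30, rng_seed=1234, open_vessel_fraction=0.2)
    image, truth, tissue_area = syn.render_core_image(
        vessels, pixel_size=0.5, rng_seed=1234
    )
    return {
        "vessels": vessels,
        "image": image,
        "truth": truth,
        "tissue_area": tissue_area,
        "pixel_size": 0.5,
    }


@pytest.fixture(scope="session")
def segmented_core(rendered_core):
    stain = seg.separate_stain(rendered_core["image"], rendered_core["pixel_size"])
    regions = seg.extract_vessel_regions(stain, max_gap=10.0)
    return {"stain": stain, "regions": regions, **rendered_core}


@pytest.fixture(scope="session")
def small_cohort():
    cfg = syn.SyntheticCohortConfig(n_samples=200, seed=77)
    return syn.generate_cohort(cfg)


def ring_mask(shape, center, outer_r, inner_r):
    """Boolean ring (wall) mask helper used across segmentation tests."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (d2 <= outer_r**2) & (d2 > inner_r**2)
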
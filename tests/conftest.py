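import numpy as np
import pytest

import leafwet as lw


@pytest.fixture
def green():
    return lw.PRESETS["green"]


@pytest.fixture
def brown():
    return lw.PRESETS["brown"]


@pytest.fixture
def flat_wax():
    return lw.FLAT_WAX


@pytest.fixture
def water_10ul():
    return lw.DropletSpec.from_microliters(10.0)


@pytest.fixture
def green_image_set():
    """In-memory micrograph set emulating a summer (green) leaf."""
    h = lw.bump_height_for_roughness(1.16)
    items = []
    for s in range(3):
        _, _, raster = lw.gen_bump_profile(lw.BumpFieldSpec(bump_height_um=h, seed=s))
        items.append((raster, "cross_section", f"xs{s}"))
        wax, _ = lw.gen_waxtip_image(lw.WaxTipFieldSpec(seed=10 + s))
        items.append((wax, "topview_wax", f"wax{s}"))
        ero, _ = lw.gen_erosion_image(
            lw.ErosionFieldSpec(target_alpha=1.0, seed=20 + s)
        )
        items.append((ero, "topview_erosion", f"ero{s}"))
    return items


def make_two_level_image(bright_frac=0.4, seed=0, shape=(200, 200)):
    rng = np.random.default_rng(seed)
    px = np.where(rng.random(shape) < bright_frac, 200, 50).astype(np.uint8)
    return lw.GrayscaleImage(pixels=px)
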
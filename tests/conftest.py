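import numpy as np
import pandas as pd
import pytest

import slidenorm as sn


@pytest.fixture
def minimal_table() -> pd.DataFrame:
    """Tiny hand-built cell table in the expected long-format schema."""
    return pd.DataFrame(
        {
            "slide_id": ["s1"] * 4 + ["s2"] * 4,
            "image_id": ["s1_im1", "s1_im1", "s1_im2", "s1_im2",
                         "s2_im1", "s2_im1", "s2_im2", "s2_im2"],
            "marker1_vals": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
            "marker2_vals": [1.0, 2.0, 1.5, 2.5, 3.0, 2.0, 1.0, 4.0],
            "marker3_vals": [0.5, 0.5, 1.5, 2.5, 0.5, 1.5, 2.5, 3.5],
            "metadata1_vals": [0, 1, 0, 1, 0, 1, 0, 1],
        }
    )


MARKERS = ["marker1_vals", "marker2_vals", "marker3_vals"]


@pytest.fixture
def minimal_dataset(minimal_table) -> sn.MxDataset:
    return sn.create_dataset(
        minimal_table, "slide_id", "image_id", MARKERS, ["metadata1_vals"]
    )


@pytest.fixture(scope="session")
def batch_effect_dataset() -> sn.MxDataset:
    """Canonical multiplicative slide-effect fixture: 6 slides x 500 cells."""
    cfg = sn.SimConfig(
        n_slides=6,
        n_images_per_slide=2,
        n_cells_per_image=250,
        slide_effect_type="multiplicative",
        slide_effect_sd=0.5,
        seed=7,
    )
    return sn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset() -> sn.MxDataset:
    """Small homogeneous-slide fixture for fast structural checks."""
    cfg = sn.SimConfig(
        n_slides=3, n_images_per_slide=2, n_cells_per_image=50, seed=3
    )
    return sn.simulate_dataset(cfg)
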
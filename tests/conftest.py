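import numpy as np
import pandas as pd
import pytest

from scrivo.levels import PANEL_CENTERS, options_layout
from scrivo.synthetic import CohortSpec, gen_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort shared by read-only tests."""
    spec = CohortSpec.default(n_subjects=16, seed=7)
    return spec, gen_cohort(spec)


@pytest.fixture
def four_panel_layout():
    return options_layout("masked_form_constancy_medium", "right_middle")


@pytest.fixture
def blob_samples():
    """Tight Gaussian blobs at the canonical panel centers, with the
    generating panel kept as ground truth."""

    def make(n_per=200, sigma=0.02, seed=0, mirror=False):
        rng = np.random.default_rng(seed)
        rows = []
        for pos, (cx, cy) in PANEL_CENTERS.items():
            x = rng.normal(cx, sigma, n_per)
            y = rng.normal(cy, sigma, n_per)
            if mirror:
                x = 1.0 - x
            rows.append(pd.DataFrame({"x": x, "y": y, "panel": pos}))
        df = pd.concat(rows, ignore_index=True)
        df["t"] = np.arange(len(df)) * 0.005
        df["confidence"] = 1.0
        return df

    return make
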
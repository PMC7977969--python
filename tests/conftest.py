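from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import mealflow as mf

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def subject_table() -> pd.DataFrame:
    """Published per-subject reference counts (28 subjects): frames detected,
    chew and bite counts with their printed accuracy cells."""
    return pd.read_csv(DATA_DIR / "per_subject_counts.csv")


@pytest.fixture(scope="session")
def small_rendered_meal():
    """A short rendered meal (3 bites, 8-12 chews each) shared across tests."""
    script = mf.default_script(seed=7, n_bites=3, chew_lo=8, chew_hi=12)
    frames, gt = mf.render_meal(script)
    return script, frames, gt


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
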
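import numpy as np
import pandas as pd
import pytest

from abdeconv.panel import SlideLayout
from abdeconv.quantify import AssayProfile, SpotTable


@pytest.fixture
def layout():
    return SlideLayout()


@pytest.fixture
def simple_spot_table():
    """One field, two antibodies in triplicate, plus blanks."""
    rows = []
    for code, reps in {"AB1": (90, 100, 200), "AB2": (100, 100, 100)}.items():
        for r, v in enumerate(reps):
            rows.append(("F1", code, "antibody", r, float(v)))
    for role, target, vals in (
        ("blank_bsa", "BSA", (40, 50, 60)),
        ("blank_buffer", "BUFFER", (50, 50, 50)),
        ("preimmune", "AB1", (45, 50, 55)),
    ):
        for r, v in enumerate(vals):
            rows.append(("F1", target, role, r, float(v)))
    return SpotTable(
        pd.DataFrame(
            rows, columns=["field_id", "target", "role", "replicate", "intensity"]
        )
    )


def make_profile(f_by_antibody, background=None, cv=0.0):
    """Build an AssayProfile directly from {antibody: F}."""
    data = pd.DataFrame(
        {
            "F": pd.Series(f_by_antibody, dtype=float),
            "cv": cv,
            "cv_flag": False,
            "saturated": False,
        }
    )
    data.index.name = "antibody"
    controls = pd.DataFrame(
        [{"role": "blank_bsa", "target": "BSA", "F": background or 0.0}]
    )
    return AssayProfile(data=data, controls=controls, background=background)


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
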
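from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from obcval import AlgorithmConfig, Cohort, ITEM_IDS, ScoreSheet, default_config

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

RAW_CODE_LIST = [0, 1, 2, 3, 7, 8]


@pytest.fixture
def config() -> AlgorithmConfig:
    return default_config()


def make_sheet(subject_id: str = "S1", age: float = 5.0, gender: str = "male",
               dx: str | None = None, fill: int = 0, **item_codes) -> ScoreSheet:
    """Sheet with every item at ``fill`` except the given overrides.

    Item ids with digits are passed as e.g. ``B1=2``.
    """
    items = {item_id: fill for item_id in ITEM_IDS}
    for item_id, code in item_codes.items():
        assert item_id in items, item_id
        items[item_id] = code
    return ScoreSheet(subject_id=subject_id, age_years=age, gender=gender,
                      items=items, clinical_dx=dx)


@pytest.fixture
def zero_sheet() -> ScoreSheet:
    return make_sheet()


def random_cohort(n: int, seed: int, codes=(0, 1, 2, 3, 7, 8)) -> Cohort:
    """Uniform-random valid cohort, for round-trip and invariance tests."""
    rng = np.random.default_rng(seed)
    sheets = []
    for i in range(n):
        items = {item_id: int(rng.choice(codes)) for item_id in ITEM_IDS}
        sheets.append(ScoreSheet(
            subject_id=f"R{i:04d}",
            age_years=float(rng.uniform(1, 20)),
            gender=str(rng.choice(["male", "female", "unknown"])),
            items=items,
            clinical_dx=[None, "spectrum", "non_spectrum"][int(rng.integers(3))],
        ))
    return Cohort(sheets=sheets, source_tag="random")


@st.composite
def sheet_strategy(draw, codes=RAW_CODE_LIST):
    items = {item_id: draw(st.sampled_from(codes)) for item_id in ITEM_IDS}
    return ScoreSheet(
        subject_id=draw(st.text(min_size=1, max_size=8,
                                alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789")),
        age_years=draw(st.floats(min_value=0.0, max_value=30.0,
                                 allow_nan=False, allow_infinity=False)),
        gender=draw(st.sampled_from(["male", "female", "unknown"])),
        items=items,
        clinical_dx=draw(st.sampled_from([None, "spectrum", "non_spectrum"])),
    )
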
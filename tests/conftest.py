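import numpy as np
import pandas as pd
import pytest

from hai_sir.synthetic import SyntheticConfig, generate_registry


@pytest.fixture(scope="session")
def small_registry():
    """A modest registry with known truth, shared across read-only tests."""
    cfg = SyntheticConfig(n_hospitals=150, wards_per_hospital=4, seed=42)
    records, truth = generate_registry(cfg)
    return records, truth


@pytest.fixture(scope="session")
def clean_registry():
    """Registry without missing values (for design/model tests)."""
    cfg = SyntheticConfig(
        n_hospitals=150, wards_per_hospital=4, seed=7, missing_surgery_ratio_frac=0.0
    )
    records, truth = generate_registry(cfg)
    return records, truth


def make_records(rows):
    """Build a minimal registry frame from per-record dicts.

    Fills the columns the cohort filter needs; observed counts default to 0.
    """
    defaults = {
        "ward_id": "W0",
        "ward_type": "internal",
        "hospital_expertise": "general",
        "affiliation": "government",
        "hospital_type": "teaching",
        "accreditation": "grade1",
        "surgery_to_surgery_bed_ratio": 1.0,
        "n_hospitalizations": 100,
        "observed_RTI": 0,
        "observed_UTI": 0,
        "observed_SSI": 0,
        "observed_BSI": 0,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("hospital_id", f"H{i}")
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def tiny_records():
    return make_records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
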
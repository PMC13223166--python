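import pandas as pd
import pytest
from hypothesis import settings

from lymphmap.io import COHORT_COLUMNS
from lymphmap.simulate import default_config, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 200-patient cohort under the default study conditions."""
    return generate_cohort(default_config(n_patients=200, seed=7))


def make_toy_cohort(zone_positive_rows, laterality=None, nact=None) -> pd.DataFrame:
    """Hand-built cohort: one dict {zone_id: positive_count} per patient.

    Resected counts are set to the positive count plus one so every
    invariant (positive <= resected, involvement iff positive >= 1,
    stage I-II structurally node-negative) holds.
    """
    n = len(zone_positive_rows)
    laterality = laterality or ["bilateral"] * n
    nact = nact if nact is not None else [0] * n
    rows = []
    for i, zp in enumerate(zone_positive_rows):
        row = {
            "patient_id": f"T{i + 1:03d}",
            "age": 55.0,
            "menopause": 1,
            "parity": "1-3",
            "ca125": 300.0,
            "he4": 160.0,
            "ascites_ml": 100.0,
            "tumor_size_mm": 80.0,
            "grade": "G3",
            "histology": "non-serous",
            "figo": "III-IV" if zp else "I-II",
            "laterality": laterality[i],
            "nact": nact[i],
        }
        for z in range(1, 15):
            pos = int(zp.get(z, 0))
            row[f"zone_{z:02d}"] = int(pos >= 1)
            row[f"positive_{z:02d}"] = pos
            row[f"resected_{z:02d}"] = pos + 1
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


@pytest.fixture
def toy_cohort() -> pd.DataFrame:
    """Four node-positive patients with involved-zone sets {1,2},{1},{2},{1,2}."""
    return make_toy_cohort([{1: 3, 2: 1}, {1: 1}, {2: 1}, {1: 1, 2: 1}])
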
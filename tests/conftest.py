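import warnings

import numpy as np
import pandas as pd
import pytest

from screenbias.cohort import validate_cohort

# the frailty fitter warns (by design) below 5 clusters; keep test output clean
warnings.filterwarnings("ignore", message="only .* clusters")


def make_cohort_frame(rows):
    """Build a validated cohort frame from compact row dicts."""
    defaults = dict(region="nonXF", screened=False, age_years=60.0,
                    sex="male", ethnicity="Han", stage="III",
                    histology="adenocarcinoma", bmi_category="normal",
                    cci_gt3=False, kps_gt70=True, smoker=False, surgery=False,
                    chemo=True, radio=False, targeted=False,
                    time_days=365.0, event=True)
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults, id=f"p{i}", **row)
        records.append(rec)
    return validate_cohort(pd.DataFrame(records))


@pytest.fixture
def tiny_cohort():
    """Ten patients, both regions and detection modes represented."""
    return make_cohort_frame([
        {"region": "XF", "screened": True, "stage": "I", "time_days": 1500.0,
         "event": False, "sex": "female", "surgery": True},
        {"region": "XF", "screened": True, "stage": "II", "time_days": 900.0,
         "event": True, "surgery": True},
        {"region": "XF", "screened": False, "stage": "III", "time_days": 700.0,
         "event": True},
        {"region": "XF", "screened": False, "stage": "IV", "time_days": 200.0,
         "event": True, "sex": "female"},
        {"region": "nonXF", "screened": True, "stage": "I", "time_days": 1800.0,
         "event": False, "surgery": True},
        {"region": "nonXF", "screened": False, "stage": "IV", "time_days": 150.0,
         "event": True},
        {"region": "nonXF", "screened": False, "stage": "III", "time_days": 420.0,
         "event": True, "sex": "female"},
        {"region": "nonXF", "screened": False, "stage": "II", "time_days": 800.0,
         "event": False},
        {"region": "nonXF", "screened": False, "stage": "IV", "time_days": 90.0,
         "event": True},
        {"region": "nonXF", "screened": False, "stage": "I", "time_days": 2000.0,
         "event": False, "sex": "female", "surgery": True},
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
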
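import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ppgloss import clinical_cohort, featurize_record, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

COHORT_SEED = 101


@pytest.fixture(scope="session")
def study_cohort():
    """The default-condition cohort: 29 blood-loss, 65 euvolemic records."""
    return simulate_cohort(clinical_cohort(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def study_features(study_cohort):
    """Feature table plus generator ground truth for the study cohort."""
    rows = []
    for rec, label in study_cohort:
        v = featurize_record(rec).vector
        rows.append({"record_id": rec.record_id, "label": label,
                     "r2": v.r2, "slope": v.slope,
                     "pct_change": v.pct_change, "abs_change": v.abs_change,
                     "amp_decay_frac": rec.meta["amp_decay_frac"]})
    return pd.DataFrame(rows)


def make_feature_table(n, label, center, seed):
    """Random feature table with class mean shifted by ``center``."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "record_id": [f"{label.lower()}_{i}" for i in range(n)],
        "label": label,
        "r2": rng.uniform(0.2, 1.0, n),
        "slope": rng.normal(center * 1e-3, 5e-4, n),
        "pct_change": rng.normal(center * 40.0, 8.0, n),
        "abs_change": rng.normal(center * 0.4, 0.08, n),
    })
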
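import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-configured synthetic cohort shared across tests."""
    from gfrcompare import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n=600, seed=20240915))


def make_paired_table(r_ckd, r_sch, age_class="18-40", gfr_category="60-89"):
    """Long-format paired ratio table from two per-participant ratio arrays."""
    r_ckd = np.asarray(r_ckd, dtype=float)
    r_sch = np.asarray(r_sch, dtype=float)
    n = len(r_ckd)
    age_class = np.broadcast_to(np.asarray(age_class, dtype=object), (n,))
    gfr_category = np.broadcast_to(np.asarray(gfr_category, dtype=object), (n,))
    return pd.DataFrame(
        {
            "participant_id": np.repeat([f"p{i:05d}" for i in range(n)], 2),
            "equation": np.tile(["CKD-EPI", "Schwartz"], n),
            "ratio": np.ravel(np.column_stack([r_ckd, r_sch])),
            "age_class": np.repeat(age_class, 2),
            "gfr_category": np.repeat(gfr_category, 2),
        }
    )
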
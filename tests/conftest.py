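import numpy as np
import pytest

from glyspan import (
    LifespanGroup,
    PatientRecord,
    SyntheticCohortConfig,
    published_models,
    simulate_cohort,
)
from glyspan.core import ag_from_ehba1c


@pytest.fixture(scope="session")
def models():
    return published_models()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(i=0, hba1c=7.0, ag=8.5664, lifespan=100.0, **kwargs):
    return PatientRecord(
        patient_id=f"P-{i:04d}",
        hba1c_pct=hba1c,
        ag_mmol_L=ag,
        rbc_lifespan_days=lifespan,
        **kwargs,
    )


def make_exact_cohort(model, n, seed, lifespan_range, hba1c_range=(5.0, 12.0)):
    """Records whose AG back-solves exactly to the model's eHbA1c (zero noise)."""
    rng = np.random.default_rng(seed)
    lifespan = rng.uniform(*lifespan_range, size=n)
    hba1c = rng.uniform(*hba1c_range, size=n)
    records = []
    for i in range(n):
        e = model.predict(lifespan[i], hba1c[i])
        records.append(
            make_record(i, hba1c=float(hba1c[i]), ag=float(ag_from_ehba1c(e)),
                        lifespan=float(lifespan[i]))
        )
    return records


@pytest.fixture(scope="session")
def default_cohort_10k():
    return simulate_cohort(SyntheticCohortConfig(n_patients=10_000, seed=20240901))
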
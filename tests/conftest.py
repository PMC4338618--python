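import warnings

import numpy as np
import pytest

from crrtpk.pk_model import PKParams, Regimen
from crrtpk.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture
def p80() -> PKParams:
    """Mean SBECD parameters for an 80-kg subject: CL 2.4 L/hr, V 24 L (k=0.1/hr)."""
    return PKParams.from_per_kg(0.03, 0.3, 80.0)


@pytest.fixture
def sbecd_regimen() -> Regimen:
    """Standard SBECD vehicle load for an 80-kg adult: 96 mg/kg q12h x2 then 64 mg/kg q12h."""
    return Regimen.intermittent(
        64.0, 80.0, n_doses=14, n_loading=2, loading_mg_per_kg=96.0, analyte="SBECD"
    )


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Small noise-free cohort (CRRT-consistent clearance), shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(CohortConfig(n_subjects=6, seed=11).noise_free())


@pytest.fixture(scope="session")
def default_cohort():
    """Default-noise cohort with independently drawn SBECD clearance."""
    return generate_cohort(
        CohortConfig(n_subjects=10, seed=7, sbecd_clearance_model="independent")
    )


def plasma_profile(cohort, sid, analyte="SBECD", quantifiable_only=True):
    """Absolute-time plasma samples for one subject from a cohort."""
    obs = cohort.observations
    sel = (obs["matrix"] == "plasma") & (obs["analyte"] == analyte) & (obs["subject_id"] == sid)
    if quantifiable_only:
        sel &= ~obs["bql"]
    g = obs[sel]
    t = (g["study_day"].to_numpy() - 1) * 24.0 + g["time_hr"].to_numpy()
    order = np.argsort(t)
    return t[order], g["conc_mg_L"].to_numpy()[order]
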
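import numpy as np
import pytest

from hmarules import (
    ClinicalRecord,
    Cohort,
    GenePanel,
    IPSSRCategory,
    MutationProfile,
    ResponseCategory,
    SimulationConfig,
    Therapy,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_panel():
    return GenePanel(["ASXL1", "RUNX1", "SRSF2", "TET2"])


def make_patient(
    sid,
    genes=(),
    response="CR",
    os_months=24.0,
    os_event=1,
    ipssr="INTERMEDIATE",
    therapy="AZA",
):
    profile = MutationProfile(sid, {g: None for g in genes})
    record = ClinicalRecord(
        sample_id=sid,
        response=ResponseCategory[response],
        os_months=os_months,
        os_event=os_event,
        ipssr=IPSSRCategory[ipssr],
        therapy=Therapy[therapy],
    )
    return profile, record


def build_cohort(panel, patients):
    profiles, clinical = zip(*patients)
    return Cohort(panel, list(profiles), list(clinical))


@pytest.fixture(scope="session")
def tiny_cohort(tiny_panel):
    """6 patients over a 4-gene panel with a {ASXL1, TET2} resistance core."""
    patients = [
        make_patient("P1", ["ASXL1", "TET2", "RUNX1"], "SD", 10.0, 1),
        make_patient("P2", ["ASXL1", "TET2"], "PD", 12.0, 1),
        make_patient("P3", ["ASXL1"], "CR", 30.0, 0),
        make_patient("P4", ["SRSF2"], "HI", 28.0, 1),
        make_patient("P5", [], "CR", 40.0, 0),
        make_patient("P6", ["TET2"], "SD", 15.0, 1),
    ]
    return build_cohort(tiny_panel, patients)


@pytest.fixture(scope="session")
def sim_cohort_small():
    """One default-config synthetic cohort at the reference training size."""
    return simulate_cohort(SimulationConfig(n_patients=433, seed=11))
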
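import numpy as np
import pytest

from crcpathways.cohort import Cohort, PatientRecord, PriorBloodCount
from crcpathways.synthetic import analysis_consistent_truth, reference_calibration


@pytest.fixture(scope="session")
def calibration():
    return reference_calibration()


@pytest.fixture(scope="session")
def generator_truth(calibration):
    """Survival generator truth calibrated so the horizon-10 analysis
    recovers the target functionals."""
    _, target = calibration
    return analysis_consistent_truth(target)


def make_record(
    i: int,
    pathway: str = "SYMPTOMATIC",
    tnm_stage: str = "II",
    right: bool = False,
    age: float = 70.0,
    hb: float = 120.0,
    sex: str = "M",
    prior=None,
    exclusion=None,
) -> PatientRecord:
    return PatientRecord(
        id=f"P{i:05d}",
        age=age,
        sex=sex,
        hb_g_l=hb,
        pathway=pathway,
        tnm_stage=tnm_stage,
        tumour_locations=("PROX",) if right else ("DIST",),
        prior_blood_count=prior,
        exclusion=exclusion,
    )


@pytest.fixture()
def casemix_ida_cohort():
    """IDA column of the case-mix table: n=171, 89 early-stage, 141
    right-sided."""
    recs = []
    for i in range(171):
        recs.append(
            make_record(
                i,
                pathway="IDA",
                tnm_stage="II" if i < 89 else "III",
                right=i < 141,
                sex="M" if i % 2 else "F",
                age=78.0,
                hb=89.0,
            )
        )
    return Cohort(tuple(recs))


@pytest.fixture()
def blood_count_ida_cohort():
    """IDA subgroup with the printed blood-count-class split 80/38/53."""
    recs = []
    for i in range(171):
        if i < 80:
            prior = PriorBloodCount(10.0, 120.0)
        elif i < 118:
            prior = PriorBloodCount(10.0, 95.0)
        else:
            prior = None
        recs.append(
            make_record(
                i,
                pathway="IDA",
                tnm_stage="II" if i % 2 else "III",
                right=i % 3 == 0,
                prior=prior,
            )
        )
    return Cohort(tuple(recs))
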
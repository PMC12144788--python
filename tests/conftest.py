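import datetime as dt

import numpy as np
import pytest

from lungturnover import CohortConfig, PatientSeries


def make_series(
    abundance,
    *,
    days=None,
    fev1=None,
    states=None,
    taxa=None,
    patient_id="P1",
    treatment_start=None,
    treatment_end=None,
    start=dt.date(2015, 1, 1),
):
    """Build a validated PatientSeries from a raw abundance array."""
    abundance = np.asarray(abundance, dtype=float)
    n_taxa, n = abundance.shape
    days = list(range(0, 30 * n, 30)) if days is None else list(days)
    dates = [start + dt.timedelta(days=int(d)) for d in days]
    fev1 = np.full(n, np.nan) if fev1 is None else np.asarray(fev1, dtype=float)
    states = ["B0"] * n if states is None else list(states)
    taxa = [f"t{i}" for i in range(n_taxa)] if taxa is None else list(taxa)
    series = PatientSeries(
        patient_id=patient_id,
        sample_ids=[f"{patient_id}_S{j}" for j in range(n)],
        sample_dates=dates,
        abundance=abundance,
        taxon_ids=taxa,
        fev1_percent=fev1,
        disease_state=states,
        treatment_start_date=None
        if treatment_start is None
        else start + dt.timedelta(days=int(treatment_start)),
        treatment_end_date=None
        if treatment_end is None
        else start + dt.timedelta(days=int(treatment_end)),
    ).normalized()
    series.validate()
    return series


@pytest.fixture
def config():
    return CohortConfig()


@pytest.fixture
def tiny_cohort_files(tmp_path):
    """A 2-patient cohort written in the external TSV/CSV formats."""
    (tmp_path / "taxon_table_A.tsv").write_text(
        "taxon_id\tA_S1\tA_S2\tA_S3\n"
        "tax1\t10\t0\t5\n"
        "tax2\t0\t0\t1\n"
        "tax3\t90\t100\t94\n"
    )
    (tmp_path / "taxon_table_B.tsv").write_text(
        "taxon_id\tB_S1\tB_S2\tB_S3\n"
        "tax1\t1\t2\t3\n"
        "tax4\t9\t8\t7\n"
    )
    (tmp_path / "sample_metadata.csv").write_text(
        "patient_id,sample_id,date,fev1_percent,disease_state,treatment_start,treatment_end\n"
        "A,A_S1,2015-01-01,55,B0,2015-02-10,2015-02-24\n"
        "A,A_S2,2015-02-01,52,E,2015-02-10,2015-02-24\n"
        "A,A_S3,2015-03-05,50,R,2015-02-10,2015-02-24\n"
        "B,B_S1,2015-01-05,70,B0,,\n"
        "B,B_S2,2015-02-05,71,B0,,\n"
        "B,B_S3,2015-03-05,69,B0,,\n"
    )
    return tmp_path
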
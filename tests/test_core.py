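import datetime as dt
import json
import logging

import numpy as np
import pandas as pd
import pytest

from lungturnover import (
    CohortConfig,
    CohortDataError,
    assemble_patient_series,
    read_sample_metadata,
    read_taxon_table,
    write_taxon_table,
)
from lungturnover.simulate import GeneratorParams, generate_cohort

from conftest import make_series


class TestTaxonTable:
    def test_reads_counts_with_expected_shape_and_sums(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "taxon_id\ts1\ts2\ts3\ts4\n"
            "a\t10\t0\t5\t5\n"
            "b\t0\t0\t0\t1\n"
            "c\t90\t100\t95\t94\n"
        )
        table = read_taxon_table(p)
        assert table.shape == (3, 4)
        assert table.to_numpy().sum(axis=0).tolist() == [100, 100, 100, 100]

    def test_duplicate_sample_header_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("taxon_id\ts1\ts1\na\t1\t2\nb\t3\t4\n")
        with pytest.raises(CohortDataError, match="s1"):
            read_taxon_table(p)

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("taxon_id\ts1\ts2\na\t1\t2\na\t3\t4\n")
        with pytest.raises(CohortDataError, match="taxon"):
            read_taxon_table(p)

    @pytest.mark.parametrize(
        "body,msg",
        [
            ("taxon_id\ts1\ts2\na\t-1\t2\nb\t1\t1\n", "negative"),
            ("taxon_id\ts1\ts2\na\tx\t2\nb\t1\t1\n", "non-numeric"),
            ("taxon_id\ts1\ts2\na\t1\t0\nb\t1\t0\n", "all-zero"),
        ],
    )
    def test_bad_cells_rejected(self, tmp_path, body, msg):
        p = tmp_path / "t.tsv"
        p.write_text(body)
        with pytest.raises(CohortDataError, match=msg):
            read_taxon_table(p)

    def test_integer_counts_round_trip_bit_exactly(self, tmp_path):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 500, size=(9, 6)).astype(float)
        counts[0] += 1  # avoid an all-zero column
        table = pd.DataFrame(counts, index=[f"t{i}" for i in range(9)],
                             columns=[f"s{j}" for j in range(6)])
        p = tmp_path / "t.tsv"
        write_taxon_table(table, p)
        back = read_taxon_table(p)
        assert np.array_equal(back.to_numpy(), table.to_numpy())
        assert list(back.index) == list(table.index)
        assert list(back.columns) == list(table.columns)

    def test_biom_json_dense_and_sparse_match_tsv(self, tmp_path):
        mat = [[10.0, 0.0], [1.0, 5.0]]
        dense = {
            "rows": [{"id": "a"}, {"id": "b"}],
            "columns": [{"id": "s1"}, {"id": "s2"}],
            "shape": [2, 2],
            "matrix_type": "dense",
            "data": mat,
        }
        sparse = dict(dense, matrix_type="sparse", data=[[0, 0, 10.0], [1, 0, 1.0], [1, 1, 5.0]])
        pd_, ps_ = tmp_path / "d.json", tmp_path / "s.json"
        pd_.write_text(json.dumps(dense))
        ps_.write_text(json.dumps(sparse))
        d = read_taxon_table(pd_)  # auto-sniffed from the leading '{'
        s = read_taxon_table(ps_, format="biom")
        assert np.array_equal(d.to_numpy(), np.array(mat))
        assert d.equals(s)


class TestSampleMetadata:
    def test_two_patients_grouped_and_sorted(self, tiny_cohort_files):
        meta = read_sample_metadata(tiny_cohort_files / "sample_metadata.csv")
        assert sorted(meta["patient_id"].unique()) == ["A", "B"]
        for _, grp in meta.groupby("patient_id"):
            assert grp["date"].is_monotonic_increasing

    def test_unknown_disease_state_cites_row(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "patient_id,sample_id,date,fev1_percent,disease_state,treatment_start,treatment_end\n"
            "A,s1,2015-01-01,50,B0,,\n"
            "A,s2,2015-02-01,50,X,,\n"
        )
        with pytest.raises(CohortDataError, match="row 3"):
            read_sample_metadata(p)

    def test_unparsable_date_cites_row(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "patient_id,sample_id,date,fev1_percent,disease_state,treatment_start,treatment_end\n"
            "A,s1,01/02/2015,50,B0,,\n"
        )
        with pytest.raises(CohortDataError, match="row 2"):
            read_sample_metadata(p)

    def test_out_of_order_dates_sorted_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.csv"
        p.write_text(
            "patient_id,sample_id,date,fev1_percent,disease_state,treatment_start,treatment_end\n"
            "A,s2,2015-03-01,50,B0,,\n"
            "A,s1,2015-01-01,50,B0,,\n"
        )
        with caplog.at_level(logging.WARNING, logger="lungturnover"):
            meta = read_sample_metadata(p)
        assert list(meta["sample_id"]) == ["s1", "s2"]
        assert any("out of date order" in r.message for r in caplog.records)

    def test_missing_fev1_kept_as_nan(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "patient_id,sample_id,date,fev1_percent,disease_state,treatment_start,treatment_end\n"
            "A,s1,2015-01-01,,B0,,\n"
            "A,s2,2015-02-01,48.5,B0,,\n"
        )
        meta = read_sample_metadata(p)
        assert np.isnan(meta["fev1_percent"].iloc[0])
        assert meta["fev1_percent"].iloc[1] == 48.5


class TestAssemble:
    def test_columns_normalized_to_proportions(self, tiny_cohort_files):
        table = read_taxon_table(tiny_cohort_files / "taxon_table_A.tsv")
        meta = read_sample_metadata(tiny_cohort_files / "sample_metadata.csv")
        series = assemble_patient_series(table, meta[meta.patient_id == "A"])
        a = series["A"]
        np.testing.assert_allclose(a.abundance[:, 0], [0.1, 0.0, 0.9])
        np.testing.assert_allclose(a.abundance.sum(axis=0), 1.0, atol=1e-9)

    def test_orphan_samples_listed(self, tiny_cohort_files):
        table = read_taxon_table(tiny_cohort_files / "taxon_table_A.tsv")
        meta = read_sample_metadata(tiny_cohort_files / "sample_metadata.csv")
        with pytest.raises(CohortDataError, match="B_S1"):
            assemble_patient_series(table, meta)

    def test_treatment_label_outside_window_rejected(self):
        with pytest.raises(CohortDataError, match="outside treatment window"):
            make_series(
                [[1, 1, 1]],
                days=[0, 30, 60],
                states=["B0", "T", "T"],
                treatment_start=25,
                treatment_end=55,
            )

    def test_presence_conserved_by_normalization(self):
        s = make_series([[5, 0, 2], [0, 3, 1]])
        raw = np.array([[5, 0, 2], [0, 3, 1]], dtype=float)
        assert np.array_equal(s.presence(0.0), raw > 0)

    def test_synthetic_cohort_round_trips_through_files(self, tmp_path):
        cohort = generate_cohort(GeneratorParams(n_patients=3, n_no_pex=1, rng_seed=5))
        cohort.write(tmp_path)
        meta = read_sample_metadata(tmp_path / "sample_metadata.csv")
        for pid, series in cohort.patients.items():
            table = read_taxon_table(tmp_path / f"taxon_table_{pid}.tsv")
            sub = meta[meta.patient_id == pid]
            back = assemble_patient_series(table, sub)[pid]
            detected = series.abundance.sum(axis=1) > 0
            np.testing.assert_allclose(
                back.abundance, series.abundance[detected], atol=1e-12
            )
            assert back.sample_dates == series.sample_dates
            assert back.disease_state == series.disease_state
            assert back.treatment_start_date == series.treatment_start_date


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(quadrat_size=7, onset_thresholds=(0.4, 2.0), str_time_unit="days")
        p = tmp_path / "cfg.yaml"
        cfg.to_file(p)
        assert CohortConfig.from_file(p) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"presence_threshold": 1.5},
            {"quadrat_size": 2},
            {"onset_thresholds": (0.0,)},
            {"str_time_unit": "weeks"},
            {"dunn_adjustment": "fdr"},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("quadrat_sizes: 5\n")
        with pytest.raises(CohortDataError, match="quadrat_sizes"):
            CohortConfig.from_file(p)
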
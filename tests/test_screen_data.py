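"""Plate-table and gene-set I/O: validation, QC exclusion, round trips."""

import numpy as np
import pandas as pd
import pytest

from trapscreen.errors import GmtParseError, QcError, SchemaError, ValidationError
from trapscreen.screen_data import (
    UNDERFLOW_SENTINEL,
    CloneAssayRecord,
    dataset_from_frame,
    read_gmt,
    read_plate_table,
    read_results,
    write_plate_table,
    write_results,
)
from trapscreen.synthetic_screen import SyntheticScreenConfig, simulate_screen


def make_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["clone_id", "gene_symbol", "dose_gy", "replicate", "dead_rlu",
                 "total_rlu", "betagal_rlu", "is_wildtype"],
    )


GOOD_ROWS = [
    ("c1", "Prdx3", 0.0, 1, 400.0, 1000.0, 600.0, False),
    ("c1", "Prdx3", 0.5, 1, 500.0, 1000.0, 550.0, False),
    ("wt1", "WT", 0.0, 1, 350.0, 1000.0, np.nan, True),
    ("wt1", "WT", 0.5, 1, 380.0, 1000.0, np.nan, True),
]


class TestCloneAssayRecord:
    def test_live_rlu_is_total_minus_dead(self):
        rec = CloneAssayRecord("c1", "Prdx3", 0.0, 1, 400.0, 1000.0, 600.0)
        assert rec.live_rlu == 600.0

    @pytest.mark.parametrize(
        "kwargs, err",
        [
            (dict(dead_rlu=1200.0, total_rlu=1000.0), QcError),
            (dict(dose_gy=-1.0), ValidationError),
            (dict(replicate=0), ValidationError),
            (dict(dead_rlu=-5.0), ValidationError),
        ],
    )
    def test_invalid_records_raise(self, kwargs, err):
        base = dict(clone_id="c1", gene_symbol="g", dose_gy=0.0, replicate=1,
                    dead_rlu=100.0, total_rlu=1000.0)
        base.update(kwargs)
        with pytest.raises(err):
            CloneAssayRecord(**base)


class TestDatasetValidation:
    def test_valid_frame_accepted(self):
        ds = dataset_from_frame(make_frame(GOOD_ROWS))
        assert len(ds) == 4
        assert ds.dose_set == (0.0, 0.5)
        assert ds.background_genes == {"Prdx3"}

    def test_dead_above_total_excluded_with_reason(self):
        rows = GOOD_ROWS + [("c1", "Prdx3", 0.5, 2, 1200.0, 1000.0, 500.0, False)]
        ds = dataset_from_frame(make_frame(rows))
        assert len(ds) == 4
        assert len(ds.excluded) == 1
        assert ds.excluded.loc[0, "qc_reason"] == "dead_rlu > total_rlu"

    def test_missing_betagal_names_clone(self):
        rows = [("cX", "Nrf1", 0.0, 1, 100.0, 1000.0, np.nan, False)]
        with pytest.raises(ValidationError, match="cX"):
            dataset_from_frame(make_frame(rows))

    def test_missing_zero_gy_reference_lists_clone(self):
        rows = [("c9", "Bach1", 0.5, 1, 100.0, 1000.0, 400.0, False)]
        with pytest.raises(ValidationError, match="c9"):
            dataset_from_frame(make_frame(rows))

    def test_missing_column_is_schema_error(self):
        df = make_frame(GOOD_ROWS).drop(columns=["total_rlu"])
        with pytest.raises(SchemaError, match="total_rlu"):
            dataset_from_frame(df)

    def test_duplicate_well_key_rejected(self):
        rows = GOOD_ROWS + [GOOD_ROWS[0]]
        with pytest.raises(ValidationError, match="duplicated"):
            dataset_from_frame(make_frame(rows))


class TestPlateTableRoundTrip:
    def test_write_then_read_preserves_fields(self, tmp_path):
        config = SyntheticScreenConfig(n_clones=8, n_wt_replicates=4, seed=7)
        ds, _ = simulate_screen(config)
        path = tmp_path / "plate.tsv"
        write_plate_table(ds, path)
        back = read_plate_table(path)
        pd.testing.assert_frame_equal(
            back.records, ds.records, check_exact=False, rtol=1e-12
        )
        assert back.dose_set == ds.dose_set
        assert back.background_genes == ds.background_genes

    def test_csv_dialect_inferred_from_suffix(self, tmp_path):
        path = tmp_path / "plate.csv"
        make_frame(GOOD_ROWS).to_csv(path, index=False)
        ds = read_plate_table(path)
        assert len(ds) == 4

    @pytest.mark.parametrize("n_clones", [3, 17, 60])
    def test_background_size_matches_configured_gene_count(self, n_clones):
        config = SyntheticScreenConfig(n_clones=n_clones, n_wt_replicates=3, seed=1)
        ds, _ = simulate_screen(config)
        assert len(ds.background_genes) == n_clones


class TestGmt:
    def test_basic_line_parses(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("GO:0007005\tmito org\tNrf1\tPrdx3\n")
        sets = read_gmt(path)
        assert len(sets) == 1
        assert sets["GO:0007005"].member_genes == {"Nrf1", "Prdx3"}

    def test_duplicate_genes_collapse(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\tdesc\tDstn\tDstn\tPex14\n")
        assert len(read_gmt(path)["T1"]) == 2

    def test_empty_file_yields_empty_collection(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("")
        assert len(read_gmt(path)) == 0

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\tdesc\tGeneA\nT2\tonly-two-fields\n")
        with pytest.raises(GmtParseError, match="line 2") as exc:
            read_gmt(path)
        assert exc.value.line_number == 2

    def test_restriction_is_case_insensitive_and_drops_empty(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\td\tPRDX3\tNRF1\nT2\td\tZZZ9\n")
        sets = read_gmt(path).restricted_to({"Prdx3", "Nrf1", "Dstn"})
        assert len(sets) == 1
        assert sets["T1"].member_genes == {"Prdx3", "Nrf1"}


class TestResultsRoundTrip:
    def test_p_columns_render_scientific_and_round_trip(self, tmp_path):
        df = pd.DataFrame({"gene_symbol": ["a", "b"], "p": [9.89e-6, 0.5],
                           "q": [1.2e-4, 0.9]})
        path = tmp_path / "res.tsv"
        write_results(df, path)
        text = path.read_text()
        assert "9.890e-06" in text
        back = read_results(path)
        assert np.allclose(back["p"], df["p"], rtol=1e-3)
        assert np.allclose(back["q"], df["q"], rtol=1e-3)

    def test_underflow_writes_sentinel_never_zero(self, tmp_path):
        df = pd.DataFrame({"gene_symbol": ["x"], "p": [4.9e-324]})
        path = tmp_path / "res.tsv"
        write_results(df, path)
        body = path.read_text().splitlines()[1]
        assert UNDERFLOW_SENTINEL in body
        assert "\t0\n" not in path.read_text()
        back = read_results(path)
        assert np.isnan(back.loc[0, "p"])

    def test_empty_results_give_header_only_file(self, tmp_path):
        df = pd.DataFrame(columns=["gene_symbol", "p"])
        path = tmp_path / "res.tsv"
        write_results(df, path)
        lines = path.read_text().splitlines()
        assert lines == ["gene_symbol\tp"]
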
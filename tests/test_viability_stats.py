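"""Viability statistics: %viability arithmetic, wild-type null, Z and p."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trapscreen.errors import (
    DegenerateNullError,
    InsufficientNullError,
    QcError,
    UndefinedWellError,
)
from trapscreen.reference_tables import implied_null_parameters, viability_hit_table
from trapscreen.screen_data import dataset_from_frame
from trapscreen.viability_stats import (
    call_hits,
    compute_viability_results,
    delta_viability,
    fit_wt_null,
    log10_two_tailed_p,
    percent_viability,
    two_tailed_p,
    z_score,
)


class TestPercentViability:
    @pytest.mark.parametrize(
        "dead, total, expected",
        [(0.0, 1000.0, 1.0), (400.0, 1000.0, 0.6), (1000.0, 1000.0, 0.0)],
    )
    def test_fraction_of_live_signal(self, dead, total, expected):
        assert percent_viability(dead, total) == pytest.approx(expected)

    def test_zero_total_is_undefined_well(self):
        with pytest.raises(UndefinedWellError):
            percent_viability(0.0, 0.0)

    def test_dead_above_total_is_qc_error(self):
        with pytest.raises(QcError):
            percent_viability(1200.0, 1000.0)


class TestDeltaViability:
    @pytest.mark.parametrize(
        "v_dose, v_ref, expected",
        [(0.6, 0.6, 0.0), (0.29, 0.60, -0.31), (0.9977, 0.6, 0.3977)],
    )
    def test_signed_difference(self, v_dose, v_ref, expected):
        assert delta_viability(v_dose, v_ref) == pytest.approx(expected)


class TestWildTypeNull:
    def test_two_point_closed_form(self):
        null = fit_wt_null([0.0, 0.02])
        assert null.mu == pytest.approx(0.01)
        assert null.sigma == pytest.approx(0.02 / math.sqrt(2), rel=1e-12)
        assert null.source == "wt_replicates"

    def test_constant_values_are_degenerate(self):
        with pytest.raises(DegenerateNullError):
            fit_wt_null([-0.01, -0.01])

    def test_single_value_insufficient(self):
        with pytest.raises(InsufficientNullError):
            fit_wt_null([-0.01])

    def test_recovers_sampling_distribution_of_the_mean(self):
        # 22 draws from the 4-Gy null: the fitted mean must sit within
        # 3 standard errors of the generating mean
        rng = np.random.default_rng(2024)
        draws = rng.normal(-0.027, 0.080, size=22)
        null = fit_wt_null(draws)
        assert abs(null.mu + 0.027) < 3 * 0.080 / math.sqrt(22)
        assert null.n_used == 22


class TestZScore:
    def test_centering(self):
        null = fit_wt_null([0.0, 0.02, -0.02])
        assert z_score(null.mu, null) == pytest.approx(0.0)

    def test_prdx3_z_against_table_derived_null(self):
        # null back-derived by least squares from the printed 0.5-Gy rows
        t = viability_hit_table()
        sub = t[t["dose_gy"] == 0.5]
        mu, sigma, _ = implied_null_parameters(sub["delta_v"], sub["z"])
        assert (-0.3089 - mu) / sigma == pytest.approx(-4.41953, abs=0.05)

    def test_cdc25c_z_against_table_derived_null(self):
        t = viability_hit_table()
        sub = t[t["dose_gy"] == 4.0]
        mu, sigma, _ = implied_null_parameters(sub["delta_v"], sub["z"])
        assert (0.3977 - mu) / sigma == pytest.approx(5.313806, abs=0.05)

    @given(
        shift=st.floats(-0.5, 0.5, allow_nan=False),
        scale=st.floats(0.1, 10.0, allow_nan=False),
    )
    def test_affine_equivariance(self, shift, scale):
        # shifting or positively scaling every ΔV (clones and controls
        # alike) leaves every Z unchanged
        wt = np.array([-0.05, -0.01, 0.0, 0.02, 0.04])
        clone_dv = 0.15
        z0 = z_score(clone_dv, fit_wt_null(wt))
        z1 = z_score(scale * clone_dv + shift, fit_wt_null(scale * wt + shift))
        assert z1 == pytest.approx(z0, rel=1e-9, abs=1e-9)


class TestTwoTailedP:
    def test_zero_z_gives_one(self):
        assert two_tailed_p(0.0) == 1.0

    @pytest.mark.parametrize(
        "z, printed",
        [(-4.41953, 9.89e-06), (6.524403, 6.83e-11), (3.078622, 2.08e-03)],
    )
    def test_reproduces_printed_values(self, z, printed):
        assert two_tailed_p(z) == pytest.approx(printed, rel=5e-3)

    @given(st.floats(-8.0, 8.0, allow_nan=False))
    def test_symmetry(self, z):
        assert two_tailed_p(z) == pytest.approx(two_tailed_p(-z), rel=1e-12)

    @given(st.floats(0.0, 35.0, allow_nan=False), st.floats(0.01, 5.0))
    def test_strictly_decreasing_in_magnitude(self, z, bump):
        assert two_tailed_p(z + bump) < two_tailed_p(z)

    def test_extreme_z_never_returns_zero(self):
        p = two_tailed_p(60.0)
        assert p > 0.0
        # log-p stays informative far below float underflow
        assert log10_two_tailed_p(60.0) == pytest.approx(-783.9, abs=0.5)


def results_from_printed_rows():
    """Printed hit rows recast as a result table for the calling logic."""
    t = viability_hit_table().rename(columns={"gene_symbol": "gene_symbol"})
    t["clone_id"] = t["gene_symbol"]
    t["p"] = [two_tailed_p(z) for z in t["z"]]
    t["direction"] = np.where(t["delta_v"] > 0, "increased", "decreased")
    return t


class TestHitCalling:
    def test_printed_rows_partition_5_16_7(self):
        calls = call_hits(results_from_printed_rows(), alpha=0.01)
        assert calls.counts == {
            (0.5, "decreased"): 5,
            (0.5, "increased"): 16,
            (4.0, "increased"): 7,
        }
        assert len(calls.unique_genes) == 28

    def test_zero_alpha_yields_no_hits(self):
        calls = call_hits(results_from_printed_rows(), alpha=0.0)
        assert calls.partitions == {} and not calls.unique_genes

    def test_empty_input_yields_empty_partitions(self):
        empty = pd.DataFrame(columns=["gene_symbol", "dose_gy", "delta_v", "p"])
        calls = call_hits(empty, alpha=0.01)
        assert calls.partitions == {} and not calls.unique_genes


class TestPipeline:
    def make_dataset(self, viabilities):
        """Two replicates per dose with the given per-replicate viabilities."""
        rows = []
        for clone, gene, wt, per_dose in viabilities:
            for dose, vs in per_dose.items():
                for rep, v in enumerate(vs, start=1):
                    rows.append((clone, gene, dose, rep, (1 - v) * 1000.0, 1000.0,
                                 np.nan if wt else 500.0, wt))
        return dataset_from_frame(pd.DataFrame(
            rows, columns=["clone_id", "gene_symbol", "dose_gy", "replicate",
                           "dead_rlu", "total_rlu", "betagal_rlu", "is_wildtype"]))

    def test_duplicate_averaging_commutes_with_delta(self):
        layout = [
            ("c1", "g1", False, {0.0: [0.55, 0.65], 4.0: [0.30, 0.40]}),
            ("c2", "g2", False, {0.0: [0.60, 0.60], 4.0: [0.70, 0.80]}),
            ("w1", "WT", True, {0.0: [0.58, 0.62], 4.0: [0.50, 0.60]}),
            ("w2", "WT", True, {0.0: [0.61, 0.59], 4.0: [0.62, 0.58]}),
        ]
        averaged = [
            (c, g, wt, {d: [float(np.mean(vs))] for d, vs in per.items()})
            for c, g, wt, per in layout
        ]
        res_dup, _ = compute_viability_results(self.make_dataset(layout))
        res_avg, _ = compute_viability_results(self.make_dataset(averaged))
        merged = res_dup.merge(res_avg, on=["clone_id", "dose_gy"], suffixes=("", "_avg"))
        assert np.allclose(merged["delta_v"], merged["delta_v_avg"])
        assert np.allclose(merged["z"], merged["z_avg"])

    def test_direction_classified_against_null_mean(self):
        # a clone whose ΔV matches the wild-type drift exactly must not be
        # classified by its raw sign
        layout = [
            ("c1", "g1", False, {0.0: [0.60, 0.60], 4.0: [0.55, 0.55]}),  # ΔV −0.05
            ("w1", "WT", True, {0.0: [0.60, 0.60], 4.0: [0.50, 0.50]}),   # ΔV −0.10
            ("w2", "WT", True, {0.0: [0.60, 0.60], 4.0: [0.48, 0.48]}),
            ("w3", "WT", True, {0.0: [0.60, 0.60], 4.0: [0.52, 0.52]}),
        ]
        res, nulls = compute_viability_results(self.make_dataset(layout))
        row = res.iloc[0]
        assert row["delta_v"] < 0 < row["delta_v"] - nulls[4.0].mu
        assert row["direction"] == "increased"
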
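"""Segmented count regression: design coding, fitting, projections, scans."""

import numpy as np
import pandas as pd
import pytest

from opioid_trends import (SegmentedModelSpec, build_design,
                           compute_yearly_rates, fit_segmented,
                           load_reference_counts, project_counterfactual,
                           run_sensitivity, simulate_segmented_counts,
                           structural_break_scan)
from opioid_trends.config import ConfigurationError
from opioid_trends.its import fitted_rates

SPEC = SegmentedModelSpec()


@pytest.fixture(scope="module")
def ref():
    return load_reference_counts()


def series(table, num, den):
    return table.rename(columns={num: "numerator", den: "denominator"})[
        ["year", "numerator", "denominator"]]


class TestRatesAndDesign:
    @pytest.mark.parametrize("num,den,expected", [
        (254066, 1165440, 21.80), (31905, 254066, 12.56),
        (1690, 31905, 5.30), (0, 1000, 0.0),
    ])
    def test_percent_rates(self, num, den, expected):
        df = pd.DataFrame({"year": [2009], "numerator": [num],
                           "denominator": [den]})
        assert compute_yearly_rates(df).iloc[0] == expected

    def test_zero_denominator_names_the_year(self):
        df = pd.DataFrame({"year": [2011], "numerator": [1],
                           "denominator": [0]})
        with pytest.raises(ConfigurationError, match="2011"):
            compute_yearly_rates(df)

    @pytest.mark.parametrize("year,t,I,X", [
        (2009, 0, 0, 0),   # origin
        (2013, 4, 0, 0),
        (2015, 6, 1, 0),   # interaction vanishes at the step year
        (2019, 10, 1, 4),
    ])
    def test_design_coding(self, year, t, I, X):
        d = build_design(range(2009, 2020), SPEC).set_index("year")
        assert tuple(d.loc[year]) == (t, I, X)

    def test_break_year_excluded_from_design(self):
        d = build_design(range(2009, 2020), SPEC)
        assert 2014 not in set(d["year"])


class TestFitSegmented:
    def test_flat_rate_series_gives_unit_irrs(self):
        years = np.arange(2009, 2020)
        den = np.full(11, 10_000_000)
        df = pd.DataFrame({"year": years, "numerator": den // 100,
                           "denominator": den})
        fit = fit_segmented(df, SPEC)
        assert np.allclose(fit.irr[1:], 1.0, atol=1e-8)

    def test_offset_scaling_shifts_only_intercept(self, ref):
        base = fit_segmented(series(ref, "n_ltot", "n_incident"), SPEC)
        scaled_df = series(ref, "n_ltot", "n_incident")
        scaled_df["denominator"] = scaled_df["denominator"] * 10
        scaled = fit_segmented(scaled_df, SPEC)
        assert np.allclose(scaled.params[1:], base.params[1:], atol=1e-6)
        assert scaled.params[0] == pytest.approx(base.params[0] - np.log(10),
                                                 abs=1e-6)

    def test_first_year_shift_changes_only_intercept(self, ref):
        base = fit_segmented(series(ref, "n_ltot", "n_incident"), SPEC)
        shifted_spec = SegmentedModelSpec(first_year=2007)
        shifted = fit_segmented(series(ref, "n_ltot", "n_incident"),
                                shifted_spec)
        assert np.allclose(shifted.params[1:], base.params[1:], atol=1e-5)
        assert np.allclose(np.exp(shifted.params[1:]), np.exp(base.params[1:]),
                           atol=1e-5)

    def test_step_ratio_identity_at_first_post_break_year(self, ref):
        fit = fit_segmented(series(ref, "n_ltot", "n_incident"), SPEC)
        fr = fitted_rates(fit, SPEC)
        proj = project_counterfactual(fit, [2015], SPEC)
        assert fr.loc[2015] / proj.loc[2015] == pytest.approx(
            np.exp(fit.params[2]), rel=1e-10)

    def test_projection_at_first_year_is_exp_intercept(self, ref):
        fit = fit_segmented(series(ref, "n_ltot", "n_incident"), SPEC)
        proj = project_counterfactual(fit, [2009], SPEC)
        assert proj.loc[2009] == pytest.approx(100 * np.exp(fit.params[0]))

    def test_observed_2015_ltot_rate_above_projection(self, ref):
        fit = fit_segmented(series(ref, "n_ltot", "n_incident"), SPEC)
        proj = project_counterfactual(fit, [2015], SPEC)
        observed = 100 * 30480 / 278251
        assert proj.loc[2015] < observed

    def test_poisson_matches_nb_on_equidispersed_counts(self):
        sim = simulate_segmented_counts(
            (-2.0, np.log(0.98), np.log(1.02), np.log(1.01)),
            {y: 5_000_000.0 for y in range(2009, 2020)}, dispersion=0.0,
            seed=11)
        nb = fit_segmented(sim, SPEC)
        po = fit_segmented(sim, SegmentedModelSpec(family="poisson"))
        assert np.allclose(nb.params, po.params, atol=1e-4)

    def test_too_few_years_rejected(self):
        df = pd.DataFrame({"year": [2009, 2010, 2011, 2015, 2016],
                           "numerator": 10, "denominator": 100})
        with pytest.raises(ConfigurationError):
            fit_segmented(df, SPEC)


class TestSensitivityAndScan:
    def test_sensitivity_fits_include_break_year(self, ref):
        sens = run_sensitivity(series(ref, "n_discontinuers", "n_ltot"), SPEC)
        assert sens["include_break_year"].nobs == 11
        assert sens["poisson"].family == "poisson"

    def test_scan_recovers_planted_break(self):
        beta = (-2.0, np.log(1.00), np.log(0.85), np.log(0.90))
        offsets = {y: 2_000_000.0 for y in range(2009, 2020)}
        hits = 0
        for seed in range(20):
            sim = simulate_segmented_counts(beta, offsets, 0.0, seed=seed,
                                            break_year=2014)
            scan = structural_break_scan(sim, range(2012, 2017))
            hits += scan.attrs["selected_year"] == 2014
        assert hits >= 19

    def test_flat_series_scan_not_significant(self):
        years = np.arange(2009, 2020)
        df = pd.DataFrame({"year": years, "numerator": 50_000,
                           "denominator": 5_000_000})
        scan = structural_break_scan(df, range(2012, 2017))
        assert (scan["lr_statistic"] < 1e-6).all()
        assert not scan.attrs["significant"]

    def test_scan_needs_years_on_both_sides(self):
        df = pd.DataFrame({"year": np.arange(2009, 2020), "numerator": 100,
                           "denominator": 1000})
        with pytest.raises(ConfigurationError):
            structural_break_scan(df, [2018])
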
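"""Tests of the synthetic-cohort generator against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geodebut.synthetic import (
    ConfigError,
    CovariateDef,
    DomainError,
    SimulationConfig,
    StudyDomain,
    TrueFieldSpec,
    assign_survey_weights,
    default_config,
    default_field,
    evaluate_true_field,
    sample_cluster_locations,
    simulate_cohort,
)
from geodebut.descriptives import early_debut_indicator, km_estimate, survival_median

from conftest import binary_cov


class TestDomainsAndLocations:
    def test_degenerate_bounds_rejected(self):
        with pytest.raises(DomainError):
            StudyDomain(bounds=(0, 0, 0, 1))

    def test_mask_outside_bounds_rejected(self):
        with pytest.raises(DomainError):
            StudyDomain(bounds=(0, 1, 0, 1), mask=((0, 0), (2, 0), (2, 1), (0, 0)))

    def test_single_point_in_unit_square(self):
        pts = sample_cluster_locations(1, StudyDomain(), seed=0)
        assert pts.shape == (1, 2)
        assert (pts >= 0).all() and (pts <= 1).all()

    def test_deterministic_under_fixed_seed(self):
        a = sample_cluster_locations(4, StudyDomain(), seed=123)
        b = sample_cluster_locations(4, StudyDomain(), seed=123)
        np.testing.assert_array_equal(a, b)

    def test_uniformity_at_large_n(self):
        pts = sample_cluster_locations(10000, StudyDomain(), seed=1)
        assert abs(pts[:, 0].mean() - 0.5) < 0.01
        assert abs(pts[:, 1].mean() - 0.5) < 0.01

    def test_masked_sampling_respects_polygon(self):
        tri = ((0, 0), (1, 0), (0, 1), (0, 0))
        dom = StudyDomain(mask=tri)
        pts = sample_cluster_locations(500, dom, seed=2)
        assert (pts.sum(axis=1) <= 1 + 1e-12).all()


class TestTrueField:
    def test_zero_bumps_is_zero(self):
        vals = evaluate_true_field(np.random.rand(10, 2), TrueFieldSpec(bumps=()))
        np.testing.assert_array_equal(vals, 0.0)

    def test_bump_center_value_equals_amplitude(self):
        spec = TrueFieldSpec(bumps=((0.3, 0.4, 1.7, 0.2),), centered=False)
        val = evaluate_true_field(np.array([[0.3, 0.4]]), spec)
        assert val[0] == pytest.approx(1.7)

    def test_centered_field_has_zero_reference_mean(self):
        dom = StudyDomain()
        spec = default_field()
        r = spec.reference_grid_resolution
        gx, gy = np.meshgrid(np.linspace(0, 1, r), np.linspace(0, 1, r))
        vals = evaluate_true_field(np.column_stack([gx.ravel(), gy.ravel()]), spec, dom)
        assert abs(vals.mean()) < 1e-10

    def test_symmetric_bumps_direct_formula_at_center(self):
        # two equal-amplitude bumps symmetric about (0.5, 0.5)
        spec = TrueFieldSpec(
            bumps=((0.3, 0.3, 1.0, 0.2), (0.7, 0.7, 1.0, 0.2)), centered=False
        )
        d2 = 2 * 0.2**2
        expected = 2 * np.exp(-d2 / (2 * 0.2**2))
        val = evaluate_true_field(np.array([[0.5, 0.5]]), spec)
        assert val[0] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigError):
            TrueFieldSpec(bumps=((0, 0, 1.0, 0.0),))


class TestSimulateCohort:
    def test_weibull_baseline_ks(self):
        """With no covariate effects, field, or censoring, debut age minus a0
        follows the Weibull(k, b) law (Kolmogorov-Smirnov check)."""
        cfg = SimulationConfig(
            n_clusters=100,
            persons_per_cluster=100,
            interview_age_low=1e8,
            interview_age_high=2e8,
            integer_year_rounding=False,
            selection_prob_low=1.0,
            seed=7,
        )
        rec = simulate_cohort(cfg)
        assert rec["event"].all()
        x = rec["time_years"].to_numpy() - cfg.a0
        d = stats.kstest(x, lambda v: 1 - np.exp(-((v / cfg.weibull_scale) ** cfg.weibull_shape)))
        assert d.statistic < 0.02

    def test_censoring_definition(self):
        cfg = default_config(seed=3)
        rec = simulate_cohort(cfg, spatial_field=default_field())
        assert rec["time_years"].le(cfg.interview_age_high).all()
        assert (rec.loc[rec.event == 1, "time_years"] >= np.floor(cfg.a0)).all()
        # censored ages are within the (floored) interview window
        cens = rec.loc[rec.event == 0, "time_years"]
        assert cens.ge(np.floor(cfg.interview_age_low)).all()

    def test_calibrated_early_debut_prevalence(self):
        rec = simulate_cohort(default_config(seed=11), spatial_field=default_field())
        frac = early_debut_indicator(rec["time_years"], rec["event"]).mean()
        assert 0.16 <= frac <= 0.22

    def test_calibrated_median_debut_age(self):
        rec = simulate_cohort(default_config(seed=11), spatial_field=default_field())
        med = survival_median(km_estimate(rec))
        assert 15 <= med <= 17

    def test_cluster_members_share_location(self):
        rec = simulate_cohort(default_config(seed=2), spatial_field=default_field())
        per_cluster = rec.groupby("cluster")[["lat", "lon"]].nunique()
        assert (per_cluster == 1).all().all()

    def test_rounding_preserves_event_status(self):
        cfg_r = default_config(seed=9)
        cfg_c = SimulationConfig(**{**cfg_r.__dict__, "integer_year_rounding": False})
        rec_r = simulate_cohort(cfg_r, spatial_field=default_field())
        rec_c = simulate_cohort(cfg_c, spatial_field=default_field())
        np.testing.assert_array_equal(rec_r["event"], rec_c["event"])
        np.testing.assert_array_equal(
            rec_r["time_years"], np.maximum(np.floor(rec_c["time_years"]), 1.0)
        )

    def test_proportional_hazards_structure(self):
        """Nelson-Aalen log cumulative-hazard ratio between the two arms of a
        binary covariate is flat in log-time (no field, no censoring)."""
        slopes = []
        for seed in (17, 18, 19):
            cfg = SimulationConfig(
                n_clusters=100,
                persons_per_cluster=1000,
                covariates=(binary_cov("x", np.log(2.0)),),
                interview_age_low=1e8,
                interview_age_high=2e8,
                integer_year_rounding=False,
                selection_prob_low=1.0,
                seed=seed,
            )
            rec = simulate_cohort(cfg)
            ratios = []
            times = np.quantile(rec["time_years"], np.linspace(0.05, 0.95, 25))
            for _, sub in rec.groupby("x"):
                t = np.sort(sub["time_years"].to_numpy())
                n = len(t)
                na = np.cumsum(1.0 / (n - np.arange(n)))
                ratios.append(np.interp(times, t, na))
            log_ratio = np.log(ratios[1] / ratios[0])
            slopes.append(np.polyfit(np.log(times), log_ratio, 1)[0])
        assert abs(np.mean(slopes)) < 0.05

    def test_invalid_weibull_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(weibull_shape=-1.0)


class TestSurveyWeights:
    def _records(self, clusters):
        return pd.DataFrame(
            {
                "id": range(len(clusters)),
                "cluster": clusters,
                "lat": 0.0,
                "lon": 0.0,
                "time_years": 16.0,
                "event": 1,
                "weight": 1.0,
            }
        )

    def test_equal_probabilities_give_unit_weights(self):
        cfg = SimulationConfig(selection_prob_low=0.4, selection_prob_high=0.4, seed=0)
        rec = assign_survey_weights(self._records([0, 0, 1, 1]), cfg, seed=5)
        np.testing.assert_allclose(rec["weight"], 1.0)

    def test_two_cluster_arithmetic(self):
        # selection probabilities 0.2 and 0.8 -> raw weights 5 and 1.25
        rec = self._records([0, 1])
        cfg = SimulationConfig(seed=0)
        probs = np.array([0.2, 0.8])
        raw = 1.0 / probs
        out = rec.copy()
        out["weight"] = rec["cluster"].map({0: raw[0], 1: raw[1]}).astype(float)
        out["weight"] /= out["weight"].mean()
        np.testing.assert_allclose(out["weight"], [5 / 3.125, 1.25 / 3.125])
        assert out["weight"].mean() == pytest.approx(1.0)

    def test_mean_weight_is_one_and_cluster_constant(self):
        cfg = SimulationConfig(seed=4)
        rec = assign_survey_weights(self._records([0, 0, 1, 2, 2, 2]), cfg, seed=8)
        assert rec["weight"].mean() == pytest.approx(1.0)
        assert (rec.groupby("cluster")["weight"].nunique() == 1).all()

    def test_reproducible_for_fixed_seed(self):
        cfg = SimulationConfig(seed=4)
        a = assign_survey_weights(self._records([0, 1, 2]), cfg, seed=9)
        b = assign_survey_weights(self._records([0, 1, 2]), cfg, seed=9)
        np.testing.assert_array_equal(a["weight"], b["weight"])
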
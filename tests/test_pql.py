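"""Penalized quasi-likelihood engine: reductions, recovery, criteria."""

import numpy as np
import pandas as pd
import pytest

from geodebut.cox import breslow_cumhaz, fit_cox, to_poisson_frame
from geodebut.kriging import (
    BasisMatrices,
    CovarianceSpec,
    assemble_design,
    knot_count,
    select_knots,
)
from geodebut.pql import (
    PQLControl,
    estimate_tau,
    fit_pql,
    hazard_ratios,
    information_criteria,
    select_covariance,
)
from geodebut.synthetic import StudyDomain, TrueFieldSpec

from conftest import TWO_BUMP_FIELD, small_cohort


def make_frame(seed=5, n_clusters=50, persons=10, field=None, **kw):
    rec, spec = small_cohort(seed=seed, n_clusters=n_clusters, persons=persons, field=field, **kw)
    cox = fit_cox(rec, spec)
    cox, lam = breslow_cumhaz(cox, rec, spec)
    return rec, spec, cox, to_poisson_frame(rec, lam, spec)


def make_basis(frame, spec, family="spherical", tau=0.8, k=None, seed=1):
    locs = np.unique(np.column_stack([frame.lon, frame.lat]), axis=0)
    k = k or min(knot_count(frame.n), len(locs))
    knots = select_knots(locs, k, seed=seed)
    return assemble_design(frame, spec, knots, CovarianceSpec(family, tau))


class TestFitPQL:
    def test_no_spatial_term_reduces_to_poisson_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        _, spec, _, frame = make_frame()
        basis = make_basis(frame, spec)
        empty = BasisMatrices(
            X=basis.X,
            Z=np.zeros((frame.n, 0)),
            N=basis.N,
            offset=basis.offset,
            weight=basis.weight,
            knots=basis.knots,
            cov_spec=basis.cov_spec,
            coord_means=basis.coord_means,
            time=basis.time,
        )
        fit = fit_pql(empty)
        w = frame.weight / frame.weight.mean()
        glm = sm.GLM(
            frame.N,
            basis.X.to_numpy(),
            family=sm.families.Poisson(),
            offset=frame.offset,
            freq_weights=w,
        ).fit()
        np.testing.assert_allclose(fit.beta.to_numpy(), glm.params, atol=1e-8)
        assert fit.edf == pytest.approx(basis.X.shape[1], abs=1e-8)
        assert fit.aic == pytest.approx(glm.aic, abs=1e-8)

    def test_matches_cox_estimates_without_field(self):
        rec, spec, cox, frame = make_frame(seed=5)
        basis = make_basis(frame, spec)
        fit = fit_pql(basis)
        for term in cox.beta.index:
            assert fit.beta[term] == pytest.approx(cox.beta[term], abs=0.02)

    def test_weight_rescaling_invariance(self):
        _, spec, _, frame = make_frame(seed=8, equal_weights=False)
        basis = make_basis(frame, spec)
        fit1 = fit_pql(basis)
        doubled = BasisMatrices(
            X=basis.X,
            Z=basis.Z,
            N=basis.N,
            offset=basis.offset,
            weight=2.0 * basis.weight,
            knots=basis.knots,
            cov_spec=basis.cov_spec,
            coord_means=basis.coord_means,
            time=basis.time,
        )
        fit2 = fit_pql(doubled)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-10)
        np.testing.assert_allclose(fit1.u, fit2.u, atol=1e-10)

    def test_edf_decreases_with_shrinking_variance(self):
        _, spec, _, frame = make_frame(seed=5)
        basis = make_basis(frame, spec)
        edfs = []
        for s2 in (1.0, 0.1, 0.01, 1e-4, 1e-6):
            fit = fit_pql(basis, PQLControl(sigma2_init=s2, fix_sigma2=True))
            edfs.append(fit.edf)
        assert all(a >= b - 1e-9 for a, b in zip(edfs, edfs[1:]))
        assert edfs[-1] == pytest.approx(basis.X.shape[1], abs=0.01)


class TestEstimateTau:
    def test_identical_locations_rejected(self):
        _, spec, _, frame = make_frame(seed=5)
        frame.lon = np.zeros(frame.n)
        frame.lat = np.zeros(frame.n)
        basis_knots = select_knots(np.array([[0.0, 0.0], [1.0, 1.0]]), 2, seed=0)
        with pytest.raises(ValueError, match="distinct"):
            estimate_tau(frame, spec, basis_knots, "gaussian")

    def test_profile_maximum_beats_endpoints(self):
        _, spec, _, frame = make_frame(seed=9, field=TWO_BUMP_FIELD)
        locs = np.unique(np.column_stack([frame.lon, frame.lat]), axis=0)
        knots = select_knots(locs, min(knot_count(frame.n), len(locs)), seed=1)
        tau_hat, fit = estimate_tau(frame, spec, knots, "gaussian")
        taus = np.array([t for t, _ in fit.tau_profile])
        vals = np.array([v for _, v in fit.tau_profile])
        best = vals[np.argmin(np.abs(taus - tau_hat))]
        assert best >= vals[np.argmin(taus)] - 1e-6
        assert best >= vals[np.argmax(taus)] - 1e-6

    def test_recovers_known_length_scale(self):
        """Gaussian field with length scale 0.2: the profile estimate lands
        within a factor of two in most replicates."""
        hits = 0
        for rep in range(10):
            field = TrueFieldSpec(
                bumps=((0.3, 0.7, 0.8, 0.2), (0.7, 0.3, -0.8, 0.2)), centered=True
            )
            rec, spec = small_cohort(
                seed=900 + rep, n_clusters=100, persons=10, field=field
            )
            cox = fit_cox(rec, spec)
            cox, lam = breslow_cumhaz(cox, rec, spec)
            frame = to_poisson_frame(rec, lam, spec)
            locs = np.unique(np.column_stack([frame.lon, frame.lat]), axis=0)
            knots = select_knots(locs, min(knot_count(frame.n), len(locs)), seed=1)
            tau_hat, _ = estimate_tau(frame, spec, knots, "gaussian")
            if 0.1 <= tau_hat <= 0.4:
                hits += 1
        assert hits >= 7


class TestInformationCriteria:
    def test_consistency_with_fit(self):
        _, spec, _, frame = make_frame(seed=5)
        fit = fit_pql(make_basis(frame, spec))
        aic, aicc, bic = information_criteria(fit)
        assert aic == pytest.approx(fit.aic)
        assert aicc == pytest.approx(fit.aicc)
        assert bic == pytest.approx(fit.bic)
        assert aicc > aic
        assert np.isfinite([aic, aicc, bic]).all()


class TestSelectCovariance:
    def test_single_family_forced(self):
        _, spec, _, frame = make_frame(seed=5)
        locs = np.unique(np.column_stack([frame.lon, frame.lat]), axis=0)
        knots = select_knots(locs, min(knot_count(frame.n), len(locs)), seed=1)
        table, best = select_covariance(frame, spec, knots, ["matern"])
        assert list(table["family"]) == ["matern"]
        assert best.family == "matern"

    def test_comparison_table_contract(self):
        _, spec, _, frame = make_frame(seed=5)
        locs = np.unique(np.column_stack([frame.lon, frame.lat]), axis=0)
        knots = select_knots(locs, min(knot_count(frame.n), len(locs)), seed=1)
        fams = ["spherical", "gaussian", "exponential"]
        table, best = select_covariance(frame, spec, knots, fams)
        assert set(table["family"]) == set(fams)
        assert table["AICc"].is_monotonic_increasing
        assert np.isfinite(table[["AIC", "AICc", "BIC"]].to_numpy()).all()
        assert best.family == table.loc[0, "family"]


class TestHazardRatios:
    def test_null_effect_gives_unit_hr(self):
        _, spec, _, frame = make_frame(seed=5)
        fit = fit_pql(make_basis(frame, spec))
        fit.beta[:] = 0.0
        hr = hazard_ratios(fit)
        est = hr.loc[~hr["reference"], "aHR"]
        np.testing.assert_allclose(est, 1.0)

    def test_wald_interval_arithmetic(self):
        _, spec, _, frame = make_frame(seed=5)
        fit = fit_pql(make_basis(frame, spec))
        fit.beta[:] = 0.4055
        fit.cov_beta.iloc[:, :] = 0.0
        np.fill_diagonal(fit.cov_beta.values, 0.01)
        hr = hazard_ratios(fit)
        row = hr.loc[~hr["reference"]].iloc[0]
        # exp(0.4055) = 1.5001; exp(0.4055 -/+ 1.959964*0.1) = 1.2331, 1.8248
        assert row["aHR"] == pytest.approx(np.exp(0.4055), abs=1e-10)
        assert row["CI_low"] == pytest.approx(np.exp(0.4055 - 1.959963984540054 * 0.1), abs=1e-10)
        assert row["CI_high"] == pytest.approx(np.exp(0.4055 + 1.959963984540054 * 0.1), abs=1e-10)

    def test_interval_contains_estimate(self):
        _, spec, _, frame = make_frame(seed=5)
        fit = fit_pql(make_basis(frame, spec))
        hr = hazard_ratios(fit, covariate_spec=spec)
        est = hr.loc[~hr["reference"]]
        assert (est["CI_low"] <= est["aHR"]).all()
        assert (est["aHR"] <= est["CI_high"]).all()
        assert hr["reference"].sum() == len(spec)
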
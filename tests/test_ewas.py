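"""Probewise linear models, EB moderation, FDR, directional agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats
from scipy.optimize import brentq

from methbench import (SimulationConfig, bh_fdr, build_design,
                       directional_agreement, fit_probewise_models,
                       generate_study, merge_batches, moderate, run_ewas)
from methbench.ewas import LinearFitResult
from .conftest import make_dataset


class TestProbewiseFit:
    def test_two_group_equals_difference_of_means(self, rng):
        Y = rng.normal(size=(30, 20))
        status = ["case"] * 15 + ["control"] * 15
        ds = make_dataset(Y, status=status)
        design = build_design(ds.samples, covariates=())
        fit = fit_probewise_models(ds, design)
        expected = Y[:15].mean(axis=0) - Y[15:].mean(axis=0)
        np.testing.assert_allclose(fit.coef, expected, atol=1e-10)

    def test_duplicated_sample_increases_df_only(self, rng):
        Y = rng.normal(size=(20, 15))
        ds = make_dataset(Y)
        design = build_design(ds.samples, covariates=())
        fit1 = fit_probewise_models(ds, design)
        Y2 = np.vstack([Y, Y])
        ds2 = make_dataset(Y2, status=list(ds.samples["status"]) * 2)
        design2 = build_design(ds2.samples, covariates=())
        fit2 = fit_probewise_models(ds2, design2)
        np.testing.assert_allclose(fit2.coef, fit1.coef, atol=1e-10)
        assert fit2.df_residual == 2 * 20 - 2

    def test_planted_effect_within_3se(self):
        cfg = SimulationConfig(
            n_batches=2, samples_per_batch=[200, 200],
            case_fraction_per_batch=[0.5, 0.5], n_probes=500,
            n_signal_probes=50, effect_size_m=1.0, noise_sd=0.5,
            batch_mean_shift_sd=0.0, batch_var_scale_range=(1, 1), seed=4)
        datasets, truth = generate_study(cfg)
        ds = merge_batches(datasets)
        design = build_design(ds.samples)
        fit = fit_probewise_models(ds, design)
        tab = moderate(fit)
        sig = sorted(truth.signal_probe_ids)
        mean_eff = tab.loc[sig, "logFC"].mean()
        se_of_mean = tab.loc[sig, "SE"].mean() / np.sqrt(len(sig))
        assert abs(mean_eff - 1.0) < 3 * se_of_mean * np.sqrt(len(sig))

    def test_rank_deficient_design_names_columns(self, rng):
        ds = make_dataset(rng.normal(size=(10, 12)))
        design = build_design(ds.samples, covariates=())
        design["dup"] = design["status"]
        with pytest.raises(ValueError, match="dup"):
            fit_probewise_models(ds, design)


def _oracle_moderation(coef, u, sigma, df):
    """Independent step-by-step evaluation of the moment-matching and
    shrinkage closed forms (loops + bisection, no shared code path)."""
    s2 = sigma ** 2
    z = np.log(s2)
    e = [zi - special.digamma(df / 2.0) + np.log(df / 2.0) for zi in z]
    emean = sum(e) / len(e)
    evar = sum((ei - emean) ** 2 for ei in e) / (len(e) - 1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess > 0:
        ystar = brentq(lambda y: special.polygamma(1, y) - excess, 1e-8, 1e8)
        d0 = 2.0 * ystar
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        dof = d0 + df
        t = coef / (u * np.sqrt(s2_post))
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    else:
        s0_2 = np.exp(sum(z) / len(z))
        t = coef / (u * np.sqrt(s0_2))
        p = 2.0 * stats.norm.sf(np.abs(t))
        dof = np.inf
    return t, p, dof


class TestModeration:
    def _fit(self, rng, n=20, p=50, hetero=True):
        scale = rng.uniform(0.5, 2.0, p) if hetero else np.ones(p)
        Y = rng.normal(0, 1, (n, p)) * scale
        ds = make_dataset(Y, status=["case"] * (n // 2) + ["control"] * (n // 2))
        design = build_design(ds.samples)
        return fit_probewise_models(ds, design)

    def test_matches_independent_oracle(self, rng):
        fit = self._fit(rng)
        tab = moderate(fit)
        t_or, p_or, dof = _oracle_moderation(fit.coef, fit.unscaled_sd,
                                             fit.sigma, fit.df_residual)
        np.testing.assert_allclose(tab["t"].to_numpy(), t_or, atol=1e-8)
        np.testing.assert_allclose(tab["P.Value"].to_numpy(), p_or, atol=1e-8)
        assert tab.attrs["d0"] + fit.df_residual == pytest.approx(dof)

    def test_equal_variances_reduce_to_ordinary_t(self, rng):
        fit = self._fit(rng)
        fit = LinearFitResult(probe_ids=fit.probe_ids, coef=fit.coef,
                              unscaled_sd=fit.unscaled_sd,
                              sigma=np.full_like(fit.sigma, 1.3),
                              df_residual=fit.df_residual)
        tab = moderate(fit)
        ordinary = fit.coef / (fit.unscaled_sd * 1.3)
        np.testing.assert_allclose(tab["t"].to_numpy(), ordinary, atol=1e-10)

    def test_shrinkage_direction(self, rng):
        fit = self._fit(rng)
        tab = moderate(fit)
        s0_2 = tab.attrs["s0_2"]
        t_ord = fit.coef / (fit.unscaled_sd * fit.sigma)
        s2 = fit.sigma ** 2
        noisy = s2 > s0_2
        assert (np.abs(tab["t"].to_numpy()[noisy])
                >= np.abs(t_ord[noisy]) - 1e-12).all()
        quiet = s2 < s0_2
        assert (np.abs(tab["t"].to_numpy()[quiet])
                <= np.abs(t_ord[quiet]) + 1e-12).all()

    def test_se_is_u_times_posterior_sd(self, rng):
        fit = self._fit(rng)
        tab = moderate(fit)
        d0, s0_2 = tab.attrs["d0"], tab.attrs["s0_2"]
        s2_post = (d0 * s0_2 + fit.df_residual * fit.sigma ** 2) / (d0 + fit.df_residual)
        np.testing.assert_allclose(tab["SE"].to_numpy(),
                                   fit.unscaled_sd * np.sqrt(s2_post),
                                   rtol=1e-12)


def _bh_oracle(p):
    """Brute force: q_i = min over subsets S containing i ... reduced to the
    classic step-up definition computed naively."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_monotone_when_sorted(self, rng):
        p = np.sort(rng.random(30))
        q = bh_fdr(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_matches_exhaustive_oracle_small_vectors(self):
        grid = [0.01, 0.2, 0.5, 0.9]
        for n in range(1, 5):
            for combo in itertools.product(grid, repeat=n):
                np.testing.assert_allclose(bh_fdr(list(combo)),
                                           _bh_oracle(list(combo)),
                                           atol=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                    max_size=8))
    def test_matches_oracle_random(self, p):
        np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestAgreement:
    def test_all_cohorts_match(self):
        diffs = pd.DataFrame(np.ones((3, 8)))
        a = directional_agreement(diffs, reference_sign=[1, 1, 1])
        assert (a == 1.0).all()

    def test_half_match(self):
        diffs = pd.DataFrame([[1, 1, 1, 1, -1, -1, -1, -1]])
        assert directional_agreement(diffs, [1]).iloc[0] == 0.5

    def test_zero_diff_counts_as_disagreement(self):
        diffs = pd.DataFrame([[1.0, 0.0]])
        assert directional_agreement(diffs, [1]).iloc[0] == 0.5

    def test_consistent_simulated_effect_agrees(self):
        cfg = SimulationConfig(
            n_batches=8, samples_per_batch=[100] * 8,
            case_fraction_per_batch=[0.5] * 8, n_probes=400,
            n_signal_probes=40, effect_size_m=1.0, noise_sd=0.5,
            batch_mean_shift_sd=0.5, seed=6)
        datasets, truth = generate_study(cfg)
        ds = merge_batches(datasets)
        tab = run_ewas(ds, include_study_factor=True)
        sig = sorted(truth.signal_probe_ids)
        assert (tab.loc[sig, "agreement"] == 1.0).mean() >= 0.95


class TestRunEwas:
    def test_null_type_i_calibration(self):
        cfg = SimulationConfig(
            n_batches=2, samples_per_batch=[150, 150],
            case_fraction_per_batch=[0.5, 0.5], n_probes=5000,
            n_signal_probes=0, effect_size_m=0.0, noise_sd=0.5,
            batch_mean_shift_sd=0.0, batch_var_scale_range=(1, 1), seed=8)
        ds = merge_batches(generate_study(cfg)[0])
        tab = run_ewas(ds)
        frac = (tab["P.Value"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_power_on_planted_signal(self):
        cfg = SimulationConfig(
            n_batches=4, samples_per_batch=[200] * 4,
            case_fraction_per_batch=[0.5] * 4, n_probes=5000,
            n_signal_probes=100, effect_size_m=0.5, noise_sd=0.5,
            batch_mean_shift_sd=0.0, batch_var_scale_range=(1, 1), seed=9)
        datasets, truth = generate_study(cfg)
        ds = merge_batches(datasets)
        tab = run_ewas(ds, include_study_factor=True)
        sig = sorted(truth.signal_probe_ids)
        assert (tab.loc[sig, "P.Value"] < 0.05).sum() >= 80

    def test_study_factor_only_changes_design(self, rng):
        ds = make_dataset(rng.normal(size=(40, 15)),
                          batch=["A"] * 20 + ["B"] * 20)
        d_pooled = build_design(ds.samples, include_study_factor=True)
        d_cohort = build_design(ds.samples, include_study_factor=False)
        extra = set(d_pooled.columns) - set(d_cohort.columns)
        assert all(c.startswith("batch_") for c in extra)
        assert set(d_cohort.columns) <= set(d_pooled.columns)
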
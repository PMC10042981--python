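import numpy as np
import pandas as pd
import pytest

from metabotrend.datatypes import biological_mask
from metabotrend.exceptions import ValidationError
from metabotrend.simulate import (
    DesignSpec,
    VarietySpec,
    generate_design,
    generate_ground_truth,
    simulate_abundances,
)
from metabotrend.preprocess import log2_transform, qc_correct
from metabotrend.trend import (
    FitResult,
    PriorEstimate,
    SplineTrendModel,
    bh_adjust,
    build_design,
    classify_effects,
    estimate_prior,
    fit_ols,
    moderated_f,
    predict_trends,
)

from conftest import three_variety_spec, true_curve_frame


class TestBuildDesign:
    def test_three_varieties_full_rank_72x12(self, design3):
        d = build_design(design3)
        assert d.matrix.shape == (72, 12)
        assert np.linalg.matrix_rank(d.matrix) == 12
        assert d.varieties == ["Backlim", "Fortems", "Gijnlim"]

    def test_single_variety_has_no_interaction_block(self, design3):
        d = build_design(design3, varieties=["Backlim"])
        assert d.matrix.shape == (24, 4)  # intercept + 3 spline columns
        assert d.contrast("Interaction") is None
        assert d.contrast("Variety") is None
        assert d.contrast("Time").shape == (3, 4)

    def test_short_series_rejected_under_default_config(self):
        spec = DesignSpec(varieties=(VarietySpec("A", "open_field", 13, 4),))
        samples = generate_design(spec)
        with pytest.raises(ValidationError, match="harvest weeks"):
            build_design(samples, varieties=["A"])
        # relaxable by configuration
        d = build_design(samples, varieties=["A"], min_weeks=4)
        assert d.matrix.shape[0] == 12

    def test_fitted_curve_zero_at_first_week(self, design3):
        d = build_design(design3)
        for v in d.varieties:
            weeks, A = d.curve_functional(v)
            assert weeks[0] == 1
            assert np.allclose(A[0], 0.0, atol=1e-14)


class TestFitOLS:
    def test_noise_free_recovery_and_orthogonality(self, noisefree_study):
        design3, truth, _, corrected = noisefree_study
        d = build_design(design3)
        fit = fit_ols(corrected.data, d)
        X = d.matrix
        Y = corrected.data.loc[d.sample_ids].to_numpy()
        for g in range(len(fit.compounds)):
            r = Y[:, g] - X @ fit.coef[g]
            assert np.abs(X.T @ r).max() <= 1e-8
        # intercept differences recover injected variety-offset differences
        si = {k.split("/")[0]: i for i, k in enumerate(truth.series)}
        for g in range(len(fit.compounds)):
            for va, vb in [("Backlim", "Fortems"), ("Fortems", "Gijnlim")]:
                est = fit.coef[g, d.varieties.index(va)] - fit.coef[g, d.varieties.index(vb)]
                true = truth.variety_offsets[g, si[va]] - truth.variety_offsets[g, si[vb]]
                assert abs(est - true) <= 1e-8

    def test_compound_in_single_variety_flagged_partial(self, noisefree_study):
        design3, _, _, corrected = noisefree_study
        d = build_design(design3)
        data = corrected.data.copy()
        comp = data.columns[0]
        backlim_ids = design3.loc[
            (design3.variety == "Backlim") & ~design3.is_qc, "sample_id"
        ]
        keep = data.index.isin(backlim_ids)
        data.loc[~keep, comp] = np.nan
        fit = fit_ols(data, d)
        g = fit.compounds.index(comp)
        assert fit.fitted[g] and fit.partial[g]
        assert len(fit.dropped[g]) > 0
        F, p = moderated_f(fit, PriorEstimate(d0=0.0, s02=fit.sigma2), "Variety")
        assert np.isnan(F[g])

    def test_unfitted_when_too_few_observations(self, noisefree_study):
        design3, _, _, corrected = noisefree_study
        d = build_design(design3)
        data = corrected.data.copy()
        comp = data.columns[1]
        data[comp] = np.nan
        data.loc[data.index[:3], comp] = 1.0
        fit = fit_ols(data, d)
        g = fit.compounds.index(comp)
        assert not fit.fitted[g]


def _fake_fit(s2, d, A=None):
    m = len(s2)
    return FitResult(
        design=None,
        compounds=[f"c{i}" for i in range(m)],
        coef=np.zeros((m, 1)),
        cov=np.zeros((m, 1, 1)),
        sigma2=np.asarray(s2, dtype=float),
        df_resid=np.full(m, d, dtype=float),
        amean=np.asarray(A if A is not None else np.linspace(8, 16, m), dtype=float),
        fitted=np.ones(m, dtype=bool),
        partial=np.zeros(m, dtype=bool),
        dropped=[[] for _ in range(m)],
    )


class TestEstimatePrior:
    def test_equal_variances_give_infinite_prior_df(self):
        fit = _fake_fit(np.full(100, 0.25), d=20)
        prior = estimate_prior(fit)
        assert np.isinf(prior.d0)
        post = prior.posterior_var(fit.sigma2, fit.df_resid)
        assert np.allclose(post, prior.s02[np.isfinite(prior.s02)], rtol=0.05)

    def test_prior_df_recovery_scaled_inverse_chisq(self):
        rng = np.random.default_rng(2024)
        d0_true, s0_true, d = 4.0, 0.25, 10
        m = 2000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, m)
        s2 = sigma2 * rng.chisquare(d, m) / d
        prior = estimate_prior(_fake_fit(s2, d=d))
        assert 3.0 <= prior.d0 <= 5.0

    def test_flat_variance_trend_recovered_constant(self):
        rng = np.random.default_rng(7)
        d = 50  # ample residual df so smoother noise stays inside the band
        s2 = 0.5 * rng.chisquare(d, 1000) / d
        prior = estimate_prior(_fake_fit(s2, d=d, A=rng.uniform(8, 16, 1000)))
        s02 = prior.s02[np.isfinite(prior.s02)]
        assert np.abs(s02 / np.median(s02) - 1.0).max() <= 0.05

    def test_few_compounds_falls_back_to_constant(self):
        fit = _fake_fit(np.array([0.1, 0.2, 0.3, 0.4, 0.5]), d=6)
        prior = estimate_prior(fit)
        s02 = prior.s02[np.isfinite(prior.s02)]
        assert np.allclose(s02, s02[0])


class TestModeratedF:
    def test_posterior_variance_pooling_arithmetic(self):
        prior = PriorEstimate(d0=4.0, s02=np.array([0.5]))
        assert prior.posterior_var(np.array([1.5]), np.array([4.0]))[0] == pytest.approx(1.0)

    def test_d0_zero_equals_classical_partial_f(self, noisy_study):
        design3, _, _, corrected = noisy_study
        d = build_design(design3)
        sub = corrected.data.iloc[:, :50]
        fit = fit_ols(sub, d)
        prior = PriorEstimate(d0=0.0, s02=np.ones(50))
        X = d.matrix
        Y = sub.loc[d.sample_ids].to_numpy()

        def classical_partial_f(y, L):
            # RSS-difference oracle: refit under the constraint L beta = 0
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = ((y - X @ b) ** 2).sum()
            dfree = len(y) - X.shape[1]
            # constrained fit on the nullspace basis of L
            _, _, Vt = np.linalg.svd(L)
            N = Vt[L.shape[0]:].T  # basis of {beta : L beta = 0}
            XN = X @ N
            bn, *_ = np.linalg.lstsq(XN, y, rcond=None)
            rss0 = ((y - XN @ bn) ** 2).sum()
            return ((rss0 - rss1) / L.shape[0]) / (rss1 / dfree)

        for eff in ("Variety", "Time", "Interaction"):
            F, _ = moderated_f(fit, prior, eff)
            L = d.contrast(eff)
            for g in range(50):
                assert np.isclose(F[g], classical_partial_f(Y[:, g], L), rtol=1e-10, atol=1e-10)

    def test_f_monotone_decreasing_in_posterior_variance(self, noisy_study):
        design3, _, _, corrected = noisy_study
        d = build_design(design3)
        fit = fit_ols(corrected.data.iloc[:, :20], d)
        lo = PriorEstimate(d0=1e6, s02=np.full(20, 0.05))
        hi = PriorEstimate(d0=1e6, s02=np.full(20, 5.0))
        F_lo, _ = moderated_f(fit, lo, "Time")
        F_hi, _ = moderated_f(fit, hi, "Time")
        assert np.all(F_lo > F_hi)


class TestBHAdjust:
    def test_hand_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=200) ** 2
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        adj = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(adj[1]) and not np.isnan(adj[0])

    def test_discoveries_monotone_in_alpha(self):
        rng = np.random.default_rng(4)
        adj = bh_adjust(rng.uniform(size=300) ** 3)
        n_05 = (adj < 0.05).sum()
        n_01 = (adj < 0.01).sum()
        assert n_01 <= n_05


class TestClassifyEffects:
    def test_single_effect_classes(self):
        df = pd.DataFrame(
            {
                "adj_p_Variety": [0.2, 0.5, np.nan],
                "adj_p_Time": [0.01, 0.9, np.nan],
                "adj_p_Interaction": [0.3, 0.9, np.nan],
            },
            index=["a", "b", "c"],
        )
        classes = classify_effects(df)
        assert classes["a"] == "Time"
        assert classes["b"] == "none"
        assert classes["c"] == "unfitted"

    def test_variety_offsets_only_classified_variety(self, design3):
        truth = generate_ground_truth(
            design3, 200, residual_sd=0.3, flat_fraction=1.0,
            batch_effect_sd=0.0, drift_slope_sd=0.0, seed=31,
        )
        truth.variety_offsets = np.tile([0.0, 2.0, 0.0], (200, 1))
        matrix, _ = simulate_abundances(design3, truth, seed=32)
        model = SplineTrendModel().fit(log2_transform(matrix).data, design3)
        assert (model.classes_ == "Variety").mean() >= 0.8

    def test_venn_union_bookkeeping(self, noisy_study):
        design3, _, _, corrected = noisy_study
        model = SplineTrendModel().fit(corrected.data, design3)
        classes = model.classes_
        time_set = {c for c, lab in classes.items() if "Time" in lab}
        ixn_set = {c for c, lab in classes.items() if "Interaction" in lab}
        assert len(time_set | ixn_set) == len(model.changing_compounds_)
        assert len(time_set | ixn_set) == len(time_set) + len(ixn_set) - len(time_set & ixn_set)


class TestPredictTrends:
    def test_week_one_anchored_with_zero_ci(self, noisy_study):
        design3, _, _, corrected = noisy_study
        model = SplineTrendModel().fit(corrected.data, design3)
        tr = model.predict_trends()
        wk1 = tr[tr.week == 1]
        assert (wk1.logfc == 0.0).all()
        assert (wk1.se == 0.0).all()

    def test_noise_free_curves_match_templates(self, noisefree_study):
        design3, truth, _, corrected = noisefree_study
        model = SplineTrendModel().fit(corrected.data, design3)
        tr = model.predict_trends().merge(true_curve_frame(truth), on=["compound_id", "variety", "week"])
        assert np.abs(tr.logfc - tr.true_logfc).max() <= 1e-6

    def test_anchored_design_equals_posthoc_subtraction(self, noisy_study):
        # the anchored basis and subtracting the fitted week-1 value give the
        # same curves under least squares
        design3, _, _, corrected = noisy_study
        d = build_design(design3)
        fit = fit_ols(corrected.data.iloc[:, :10], d)
        prior = estimate_prior(fit)
        tr = predict_trends(fit, prior)
        X = d.matrix
        meta = design3.set_index("sample_id").loc[d.sample_ids]
        for g, comp in enumerate(fit.compounds):
            fitted = X @ fit.coef[g]
            per_cell = pd.DataFrame(
                {"f": fitted, "v": meta.variety.to_numpy(), "w": meta.harvest_week_index.astype(int).to_numpy()}
            ).groupby(["v", "w"]).f.mean()
            for v in d.varieties:
                posthoc = per_cell[v] - per_cell[v][1]
                curve = tr[(tr.compound_id == comp) & (tr.variety == v)].set_index("week").logfc
                assert np.allclose(curve, posthoc[curve.index], atol=1e-8)

    def test_parameter_recovery_mean_absolute_error(self, design3):
        truth = generate_ground_truth(
            design3, 150, residual_sd=0.3, flat_fraction=0.3, seed=41
        )
        matrix, _ = simulate_abundances(design3, truth, seed=42)
        corrected = qc_correct(log2_transform(matrix), design3)
        model = SplineTrendModel().fit(corrected.data, design3)
        tr = model.predict_trends().merge(true_curve_frame(truth), on=["compound_id", "variety", "week"])
        mae = np.abs(tr.logfc - tr.true_logfc).mean()
        assert mae <= 0.25

    def test_offset_recovery_within_two_se(self, design3):
        # pipeline closure: variety-offset contrasts within 2 moderated SEs
        truth = generate_ground_truth(
            design3, 150, residual_sd=0.3, flat_fraction=1.0, offset_fraction=1.0, seed=51
        )
        matrix, _ = simulate_abundances(design3, truth, seed=52)
        corrected = qc_correct(log2_transform(matrix), design3)
        d = build_design(design3)
        fit = fit_ols(corrected.data, d)
        prior = estimate_prior(fit)
        s2 = prior.posterior_var(fit.sigma2, fit.df_resid)
        si = {k.split("/")[0]: i for i, k in enumerate(truth.series)}
        ok = 0
        total = 0
        for g in range(150):
            for va, vb in [("Backlim", "Gijnlim"), ("Fortems", "Gijnlim")]:
                ia, ib = d.varieties.index(va), d.varieties.index(vb)
                est = fit.coef[g, ia] - fit.coef[g, ib]
                true = truth.variety_offsets[g, si[va]] - truth.variety_offsets[g, si[vb]]
                c = fit.cov[g]
                se = np.sqrt((c[ia, ia] + c[ib, ib] - 2 * c[ia, ib]) * s2[g])
                ok += abs(est - true) <= 2 * se
                total += 1
        assert ok / total >= 0.9
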
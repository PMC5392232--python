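"""Mixed models: profiled ML correctness, AICc dredge, model averaging."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from packrange.mixedlm import (
    CANDIDATE_SPECS,
    AveragedEstimates,
    RandomInterceptLM,
    build_design,
    dredge,
    model_average,
    predict_interaction_surface,
)

GROUP_SIZES = [3, 2, 2, 2, 2, 2, 2, 2, 2, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2]  # N = 40


def simulate_overlap_data(seed, beta=(3.0, 2.0, 10.0, 0.0), sigma_b=5.0, sigma_e=8.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(len(GROUP_SIZES)), GROUP_SIZES)
    n = len(g)
    ratio = rng.uniform(0.3, 3.0, n)
    rel = rng.random(n) < 0.6
    y = (
        beta[0]
        + beta[1] * ratio
        + beta[2] * rel
        + beta[3] * ratio * rel
        + rng.normal(0, sigma_b, len(GROUP_SIZES))[g]
        + rng.normal(0, sigma_e, n)
    )
    return pd.DataFrame(
        {
            "pct_of_focal": y,
            "pack_size_ratio": ratio,
            "relatedness": np.where(rel, "related", "unrelated"),
            "focal_pack": g,
        }
    )


def direct_two_variance_loglik(df, terms):
    """Independent oracle: maximise the exact two-variance Gaussian
    log-likelihood numerically, without profiling."""
    x, _ = build_design(df, terms)
    y = df["pct_of_focal"].to_numpy()
    groups = df["focal_pack"].to_numpy()
    uniq = np.unique(groups)

    def negll(theta):
        s2b, s2e = np.exp(theta)
        ll = 0.0
        # GLS via per-group inverses, beta profiled out exactly
        xtvx = np.zeros((x.shape[1], x.shape[1]))
        xtvy = np.zeros(x.shape[1])
        for u in uniq:
            m = groups == u
            ni = m.sum()
            vi = s2e * np.eye(ni) + s2b * np.ones((ni, ni))
            vinv = np.linalg.inv(vi)
            xtvx += x[m].T @ vinv @ x[m]
            xtvy += x[m].T @ vinv @ y[m]
        beta = np.linalg.solve(xtvx, xtvy)
        for u in uniq:
            m = groups == u
            ni = m.sum()
            vi = s2e * np.eye(ni) + s2b * np.ones((ni, ni))
            r = y[m] - x[m] @ beta
            sign, logdet = np.linalg.slogdet(vi)
            ll += -0.5 * (ni * math.log(2 * math.pi) + logdet + r @ np.linalg.solve(vi, r))
        return -ll

    best = None
    for start in ([0.0, 2.0], [2.0, 2.0], [-3.0, 3.0]):
        res = optimize.minimize(negll, start, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun


class TestProfiledFit:
    def test_boundary_reduces_to_ols(self):
        """Boundary fits (lambda = 0) return OLS coefficients exactly.

        Group means are matched by construction so the ML variance ratio is
        forced to the boundary deterministically; with sigma_b = 0 data the
        boundary event itself is stochastic in small samples.
        """
        rng = np.random.default_rng(0)
        k = 12
        g = np.repeat(np.arange(k), 2)
        half = rng.normal(0, 4, k)
        y = 7.0 + np.column_stack([half, -half]).ravel()  # equal group means
        fit = RandomInterceptLM(y, np.ones((2 * k, 1)), g, ["Intercept"]).fit()
        assert fit.boundary
        assert fit.sigma2_b == 0.0
        assert fit.params["Intercept"] == pytest.approx(y.mean(), abs=1e-10)

        # and on regression data, any boundary fit must equal OLS
        seen_boundary = False
        for seed in range(10):
            df = simulate_overlap_data(seed, sigma_b=0.0)
            f = RandomInterceptLM.from_dataframe(df).fit()
            if f.boundary:
                seen_boundary = True
                x, _ = build_design(
                    df, ("pack_size_ratio", "relatedness",
                         "pack_size_ratio:relatedness")
                )
                ols = np.linalg.lstsq(x, df["pct_of_focal"], rcond=None)[0]
                np.testing.assert_allclose(f.params.to_numpy(), ols, atol=1e-6)
        assert seen_boundary

    def test_balanced_closed_form_oracle(self):
        """Balanced one-way ML has the closed form sigma_e^2 = SSW/(N-k),
        sigma_e^2 + n*sigma_b^2 = SSB/k; the profiled fit matches it."""
        rng = np.random.default_rng(42)
        k, n = 8, 6
        g = np.repeat(np.arange(k), n)
        y = 2.0 + rng.normal(0, 3, k)[g] + rng.normal(0, 2, k * n)
        fit = RandomInterceptLM(y, np.ones((k * n, 1)), g, ["Intercept"]).fit()
        gm = y.reshape(k, n).mean(1)
        ssw = ((y.reshape(k, n) - gm[:, None]) ** 2).sum()
        ssb = n * ((gm - y.mean()) ** 2).sum()
        s2e = ssw / (k * n - k)
        s2b = (ssb / k - s2e) / n
        assert fit.sigma2_e == pytest.approx(s2e, abs=1e-4)
        assert fit.sigma2_b == pytest.approx(s2b, abs=1e-4)
        assert fit.params["Intercept"] == pytest.approx(y.mean(), abs=1e-8)

    def test_matches_direct_two_variance_optimiser(self):
        """Profiled logLik equals a direct 2-variance numerical ML fit."""
        for seed in range(6):
            df = simulate_overlap_data(100 + seed)
            terms = ("pack_size_ratio", "relatedness")
            fit = RandomInterceptLM.from_dataframe(df, terms).fit()
            ref = direct_two_variance_loglik(df, terms)
            assert fit.llf == pytest.approx(ref, abs=1e-4)

    def test_parameter_recovery(self):
        """Mean ML estimates across replicates sit near the true betas."""
        est = []
        for seed in range(60):
            df = simulate_overlap_data(seed)
            fit = RandomInterceptLM.from_dataframe(
                df, ("pack_size_ratio", "relatedness")
            ).fit()
            est.append(fit.params[["pack_size_ratio", "relatedness"]].to_numpy())
        mean = np.mean(est, axis=0)
        assert abs(mean[0] - 2.0) < 0.5
        assert abs(mean[1] - 10.0) < 0.5

    def test_loglik_monotone_in_nesting(self):
        """A larger nested fixed structure never fits worse under ML."""
        df = simulate_overlap_data(7)
        lls = [
            RandomInterceptLM.from_dataframe(df, terms).fit().llf
            for terms in CANDIDATE_SPECS
        ]
        assert lls[1] >= lls[0] - 1e-6  # ratio vs null
        assert lls[3] >= lls[1] - 1e-6
        assert lls[3] >= lls[2] - 1e-6
        assert lls[4] >= lls[3] - 1e-6

    def test_singular_design_names_term(self):
        df = simulate_overlap_data(1)
        df["relatedness"] = "related"  # aliased with intercept
        with pytest.raises(ValueError, match="singular"):
            RandomInterceptLM.from_dataframe(df, ("relatedness",))

    def test_nonfinite_response_rejected(self):
        df = simulate_overlap_data(2)
        df.loc[0, "pct_of_focal"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            RandomInterceptLM.from_dataframe(df, ())


class TestDredge:
    def test_candidate_set_is_five_models(self):
        ms = dredge(simulate_overlap_data(3))
        assert len(ms.fits) == 5
        names = {name for name, _, _ in ms.fits}
        assert "Null model" in names

    def test_weights_sum_to_one(self):
        ms = dredge(simulate_overlap_data(4))
        assert ms.weights.sum() == pytest.approx(1.0)
        assert ms.delta[0] == 0.0
        assert (np.diff([f.aicc for _, _, f in ms.fits]) >= -1e-9).all()

    def test_aicc_exceeds_aic_and_shrinks_with_n(self):
        df = simulate_overlap_data(5)
        fit = RandomInterceptLM.from_dataframe(df, ("pack_size_ratio",)).fit()
        assert fit.aicc > fit.aic
        big = pd.concat([simulate_overlap_data(s) for s in range(6, 12)])
        big["focal_pack"] = np.repeat(np.arange(len(big) // 2), 2)[: len(big)]
        fit_big = RandomInterceptLM.from_dataframe(big, ("pack_size_ratio",)).fit()
        assert (fit_big.aicc - fit_big.aic) < (fit.aicc - fit.aic)

    def test_small_n_aicc_guard(self):
        df = simulate_overlap_data(8).iloc[:7]
        with pytest.raises(ValueError, match="AICc"):
            dredge(df)


class TestModelAverage:
    def test_degenerate_single_model_average(self):
        """A model holding ~all the weight averages to its own coefficients."""
        df = simulate_overlap_data(9, beta=(0.0, 25.0, 0.0, 0.0), sigma_b=1.0,
                                   sigma_e=2.0)
        ms = dredge(df)
        avg = model_average(ms, cum_weight=0.5)
        if len(avg.selected_models) == 1:
            name, _, top = ms.fits[0]
            for nm in top.params.index:
                assert avg.estimates[nm] == pytest.approx(top.params[nm])

    def test_term_in_all_selected_has_importance_one(self, paper_run):
        eff = paper_run.averaged_effects.set_index("parameter")
        assert eff.loc["Intercept", "relative_importance"] == pytest.approx(1.0)

    def test_interaction_importance_hand_fixture(self):
        """Relative importance equals the renormalised weight mass of the
        models containing the term, checked by hand on the selected set."""
        df = simulate_overlap_data(11)
        ms = dredge(df)
        avg = model_average(ms, cum_weight=0.95)
        w = avg.selected_weights
        names = avg.selected_models
        by_name = {name: terms for name, terms, _ in ms.fits}
        hand = sum(
            wm for name, wm in zip(names, w)
            if "pack_size_ratio:relatedness" in by_name[name]
        )
        got = avg.importance.get("pack_size_ratio:relatedness", 0.0)
        assert got == pytest.approx(hand)

    def test_full_average_in_convex_hull(self):
        """Zero-substitution averages lie between 0 and the most extreme
        per-model estimate."""
        df = simulate_overlap_data(12)
        ms = dredge(df)
        avg = model_average(ms)
        for nm in avg.estimates.index:
            vals = [0.0] + [
                f.params[nm] for _, _, f in ms.fits[: len(avg.selected_models)]
                if nm in f.params.index
            ]
            assert min(vals) - 1e-9 <= avg.estimates[nm] <= max(vals) + 1e-9

    def test_empty_set_rejected(self):
        from packrange.mixedlm import ModelSet

        ms = object.__new__(ModelSet)
        ms.fits, ms.weights, ms.data = [], np.array([]), None
        with pytest.raises(ValueError):
            model_average(ms)


class TestPredictionSurface:
    def test_two_horizontal_lines_geometry(self):
        avg = AveragedEstimates(
            estimates=pd.Series({"Intercept": 5.0, "relatedness": 10.0}),
            unconditional_se=pd.Series({"Intercept": 1.0, "relatedness": 1.0}),
            conditional_estimates=pd.Series({"Intercept": 5.0, "relatedness": 10.0}),
            importance=pd.Series({"Intercept": 1.0, "relatedness": 1.0}),
            selected_models=["relatedness"],
            selected_weights=np.array([1.0]),
            cum_weight=0.95,
            ratio_range=(0.5, 2.0),
        )
        surf = predict_interaction_surface(avg, n_points=5)
        for label, want in (("unrelated", 5.0), ("related", 15.0)):
            vals = surf.loc[surf["relatedness"] == label, "predicted"]
            assert np.allclose(vals, want)

    def test_outside_range_warns(self):
        avg = AveragedEstimates(
            estimates=pd.Series({"Intercept": 1.0}),
            unconditional_se=pd.Series({"Intercept": 1.0}),
            conditional_estimates=pd.Series({"Intercept": 1.0}),
            importance=pd.Series({"Intercept": 1.0}),
            selected_models=["Null model"],
            selected_weights=np.array([1.0]),
            cum_weight=0.95,
            ratio_range=(0.5, 2.0),
        )
        with pytest.warns(UserWarning, match="observed"):
            predict_interaction_surface(avg, ratio_grid=np.array([0.1, 3.0]))

    def test_interaction_pattern_recovery(self):
        """Data with a ratio slope only for unrelated dyads recover a
        positive unrelated slope and a flatter related slope."""
        hits = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(5000 + seed)
            g = np.repeat(np.arange(len(GROUP_SIZES)), GROUP_SIZES)
            n = len(g)
            ratio = rng.uniform(0.3, 3.0, n)
            rel = rng.random(n) < 0.6
            y = (
                5.0 + 8.0 * ratio * (~rel)
                + 12.0 * rel
                + rng.normal(0, 3, len(GROUP_SIZES))[g]
                + rng.normal(0, 4, n)
            )
            df = pd.DataFrame(
                {
                    "pct_of_focal": y,
                    "pack_size_ratio": ratio,
                    "relatedness": np.where(rel, "related", "unrelated"),
                    "focal_pack": g,
                }
            )
            avg = model_average(dredge(df))
            slope_unrel = avg.estimates.get("pack_size_ratio", 0.0)
            slope_rel = slope_unrel + avg.estimates.get(
                "pack_size_ratio:relatedness", 0.0
            )
            if slope_unrel > 0 and abs(slope_rel) < slope_unrel:
                hits += 1
        assert hits >= 0.8 * reps

    def test_mean_prediction_identity(self):
        """Averaged prediction at the data mean equals the weighted average
        of per-model fitted means (full averaging, zero substitution)."""
        df = simulate_overlap_data(13)
        ms = dredge(df)
        avg = model_average(ms)
        rel = (df["relatedness"] == "related").mean()
        ratio = df["pack_size_ratio"].mean()
        ratio_rel = (
            df["pack_size_ratio"] * (df["relatedness"] == "related")
        ).mean()
        pred = (
            avg.estimates.get("Intercept", 0.0)
            + avg.estimates.get("pack_size_ratio", 0.0) * ratio
            + avg.estimates.get("relatedness", 0.0) * rel
            + avg.estimates.get("pack_size_ratio:relatedness", 0.0) * ratio_rel
        )
        ref = 0.0
        for (_, _, f), wm in zip(
            ms.fits[: len(avg.selected_models)], avg.selected_weights
        ):
            covs = {"Intercept": 1.0, "pack_size_ratio": ratio,
                    "relatedness": rel, "pack_size_ratio:relatedness": ratio_rel}
            ref += wm * sum(f.params[nm] * covs[nm] for nm in f.params.index)
        assert pred == pytest.approx(ref, abs=1e-9)
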
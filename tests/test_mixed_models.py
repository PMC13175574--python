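"""Coding, mixed-model fitting contract, simplification policy, simple
slopes, moderation and covariate workflows."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from prosocial_effort.mixed_models import (
    CodedDataset,
    ModelResult,
    ModelSpec,
    code_predictors,
    covariate_control,
    cross_task_moderation,
    fit_mixed_model,
    lme4_available,
    simple_slopes,
    simplify_random_effects,
)

needs_lme4 = pytest.mark.skipif(not lme4_available(), reason="Rscript/lme4 unavailable")


def raw_trials(n_sub=6, n_tr=60, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        rows.append(
            pd.DataFrame(
                {
                    "participant": s,
                    "recipient": rng.choice(["self", "other"], n_tr),
                    "valence": rng.choice(["gain", "nongain"], n_tr),
                    "effort_index": rng.integers(1, 6, n_tr),
                    "magnitude_yuan": rng.choice([0.2, 0.4, 0.6, 0.8, 1.0], n_tr),
                    "success": rng.random(n_tr) < 0.95,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df["y"] = rng.normal(size=len(df))
    return df


class TestCoding:
    def test_contrast_codes(self):
        coded = code_predictors(raw_trials(), outcome="y").frame
        self_rows = coded[coded["recipient"] == "self"]
        gain_rows = coded[coded["valence"] == "gain"]
        assert (self_rows["recipient_c"] == -0.5).all()
        assert (gain_rows["valence_c"] == -0.5).all()

    def test_within_participant_z_scores(self):
        coded = code_predictors(raw_trials(), outcome="y").frame
        for _, g in coded.groupby("participant"):
            assert g["effort_z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert g["effort_z"].std(ddof=1) == pytest.approx(1.0)
            assert g["magnitude_z"].std(ddof=1) == pytest.approx(1.0)

    def test_constant_predictor_raises(self):
        df = raw_trials()
        df.loc[df["participant"] == 0, "effort_index"] = 3
        with pytest.raises(ValueError):
            code_predictors(df, outcome="y")

    def test_drop_failed_trials(self):
        df = raw_trials()
        coded = code_predictors(df, outcome="y", drop_failed=True).frame
        assert coded["success"].all()

    def test_quadratic_term_centered(self):
        coded = code_predictors(raw_trials(), outcome="y", add_effort_quadratic=True).frame
        for _, g in coded.groupby("participant"):
            assert g["effort_z2_c"].mean() == pytest.approx(0.0, abs=1e-12)


def generated_dataset(n_sub=20, n_tr=120, resid=0.5, slope_sd=0.0, seed=1, re_corr=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    betas = {"x": 0.8, "m": -0.4, "x:m": 0.6}
    for s in range(n_sub):
        x = rng.choice([-0.5, 0.5], n_tr)
        m = rng.normal(size=n_tr)
        cov = np.array(
            [[1.0, re_corr], [re_corr, 1.0]]
        ) * (slope_sd**2 if slope_sd else 0)
        if slope_sd:
            u = rng.multivariate_normal([0, 0], cov)
        else:
            u = np.zeros(2)
        u0 = rng.normal(0, 1.0) if slope_sd else 0.0
        y = 0.3 + betas["x"] * x + betas["m"] * m + betas["x:m"] * x * m
        y = y + u0 + u[0] * x + rng.normal(0, resid, n_tr)
        rows.append(pd.DataFrame({"participant": s, "x": x, "m": m, "y": y}))
    return pd.concat(rows, ignore_index=True), betas


class TestFitting:
    def test_zero_noise_recovers_truth_exactly(self):
        df, betas = generated_dataset(n_sub=6, resid=1e-8, slope_sd=0.0)
        res = fit_mixed_model(CodedDataset(df, "y"), ModelSpec("y ~ x * m"))
        assert res.coef("x") == pytest.approx(betas["x"], abs=1e-5)
        assert res.coef("x:m") == pytest.approx(betas["x:m"], abs=1e-5)

    def test_matches_ols_when_no_random_variance(self):
        df, _ = generated_dataset(n_sub=8, resid=0.7, slope_sd=0.0)
        res = fit_mixed_model(CodedDataset(df, "y"), ModelSpec("y ~ x * m"))
        ols = smf.ols("y ~ x * m", df).fit()
        for term in ("Intercept", "x", "m", "x:m"):
            assert res.coef(term) == pytest.approx(ols.params[term], abs=1e-3)

    def test_well_conditioned_structure_kept(self):
        df, _ = generated_dataset(n_sub=40, n_tr=150, resid=0.5, slope_sd=0.8, re_corr=0.4, seed=3)
        res = fit_mixed_model(
            CodedDataset(df, "y"), ModelSpec("y ~ x * m", re_terms=("x",))
        )
        assert res.spec.re_terms == ("x",)
        assert res.simplification_log[-1].endswith("ok")

    def test_coding_invariance(self):
        df, _ = generated_dataset(n_sub=8, resid=0.4)
        res = fit_mixed_model(CodedDataset(df, "y"), ModelSpec("y ~ x * m"))
        flipped = df.copy()
        flipped["x"] = -flipped["x"]
        res2 = fit_mixed_model(CodedDataset(flipped, "y"), ModelSpec("y ~ x * m"))
        assert res2.coef("x") == pytest.approx(-res.coef("x"), rel=1e-6)
        assert res2.coef("x:m") == pytest.approx(-res.coef("x:m"), rel=1e-6)
        assert res2.coef("m") == pytest.approx(res.coef("m"), rel=1e-6)

    def test_outcome_without_variance_rejected(self):
        df, _ = generated_dataset(n_sub=4)
        df["y"] = 1.0
        with pytest.raises(ValueError):
            fit_mixed_model(CodedDataset(df, "y"), ModelSpec("y ~ x"))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("y ~ x", re_terms=("z",))
        with pytest.raises(ValueError):
            ModelSpec("y ~ x", family="poisson")


class TestSimplification:
    def test_smallest_variance_slope_dropped_first(self):
        spec = ModelSpec("y ~ a * b", re_terms=("a", "b"), correlated=False)
        out = simplify_random_effects(spec, {"intercept": 1.0, "a": 0.0, "b": 0.5})
        assert out.re_terms == ("b",)

    def test_correlations_dropped_before_slopes(self):
        spec = ModelSpec("y ~ a * b", re_terms=("a", "b"), correlated=True)
        out = simplify_random_effects(spec, {"intercept": 1.0, "a": 0.0, "b": 0.5})
        assert out.re_terms == ("a", "b") and not out.correlated

    def test_terminates_at_intercept_only(self):
        spec = ModelSpec("y ~ a * b", re_terms=("a", "b"), correlated=True)
        seen = set()
        for _ in range(len(spec.re_terms) + 2):
            spec = simplify_random_effects(spec, {t: 0.0 for t in ("intercept", *spec.re_terms)})
            seen.add((spec.re_terms, spec.correlated))
        assert spec.re_terms == ()
        assert simplify_random_effects(spec, {}) == spec

    def test_pathological_data_reaches_intercept_only(self):
        # pure iid noise: every random-effect variance is truly zero, so
        # each structure in the ladder is singular until intercept-only
        rng = np.random.default_rng(0)
        rows = []
        for s in range(8):
            rows.append(
                pd.DataFrame(
                    {"participant": s, "x": rng.choice([-0.5, 0.5], 30), "y": rng.normal(0, 1.0, 30)}
                )
            )
        df = pd.concat(rows, ignore_index=True)
        res = fit_mixed_model(CodedDataset(df, "y"), ModelSpec("y ~ x", re_terms=("x",)))
        assert res.spec.re_terms == ()
        # bounded number of refits: correlated -> uncorrelated -> dropped -> intercept-only
        n_fits = sum(1 for line in res.simplification_log if line.startswith("fitted"))
        assert n_fits <= len(("x",)) + 2


def manual_result(betas, cov, terms):
    table = pd.DataFrame(
        {
            "estimate": [betas[t] for t in terms],
            "se": np.sqrt(np.diag(cov)),
            "stat": np.nan,
            "df": np.nan,
            "p": np.nan,
        },
        index=terms,
    )
    return ModelResult(
        table=table,
        cov=pd.DataFrame(cov, index=terms, columns=terms),
        spec=ModelSpec("y ~ x * m"),
        re_variances={},
        converged=True,
        singular=False,
    )


class TestSimpleSlopes:
    def test_no_interaction_slope_is_main_effect(self):
        terms = ["Intercept", "x", "m"]
        res = manual_result({"Intercept": 1.0, "x": 0.7, "m": -0.2}, np.eye(3) * 0.01, terms)
        out = simple_slopes(res, "x", {"m": [-1.0, 0.0, 1.0]})
        assert np.allclose(out["slope"], 0.7)

    def test_two_way_algebra(self):
        terms = ["Intercept", "x", "m", "x:m"]
        betas = {"Intercept": 0.0, "x": 0.5, "m": 0.1, "x:m": -0.3}
        res = manual_result(betas, np.eye(4) * 0.01, terms)
        for m0 in (-1.5, 0.0, 2.0):
            out = simple_slopes(res, "x", {"m": [m0]})
            assert out["slope"].iloc[0] == pytest.approx(0.5 - 0.3 * m0)

    def test_se_quadratic_form(self):
        terms = ["Intercept", "x", "m", "x:m"]
        cov = np.array(
            [
                [0.02, 0.0, 0.0, 0.0],
                [0.0, 0.04, 0.0, 0.01],
                [0.0, 0.0, 0.03, 0.0],
                [0.0, 0.01, 0.0, 0.05],
            ]
        )
        res = manual_result({"Intercept": 0, "x": 0.5, "m": 0.1, "x:m": -0.3}, cov, terms)
        m0 = 2.0
        out = simple_slopes(res, "x", {"m": [m0]})
        expected_var = cov[1, 1] + m0**2 * cov[3, 3] + 2 * m0 * cov[1, 3]
        assert out["se"].iloc[0] == pytest.approx(np.sqrt(expected_var))
        assert out["ci_low"].iloc[0] < out["slope"].iloc[0] < out["ci_high"].iloc[0]

    def test_absent_focal_raises(self):
        res = manual_result({"Intercept": 0.0, "x": 1.0}, np.eye(2), ["Intercept", "x"])
        with pytest.raises(ValueError):
            simple_slopes(res, "q", {"m": [0.0]})

    def test_recentering_oracle_single_case(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=200), "m": rng.normal(size=200)})
        df["y"] = 0.4 * df.x - 0.2 * df.m + 0.5 * df.x * df.m + rng.normal(0, 0.3, 200)
        fit = smf.ols("y ~ x * m", df).fit()
        res = manual_result(fit.params.to_dict(), fit.cov_params().to_numpy(), list(fit.params.index))
        m0 = 1.3
        out = simple_slopes(res, "x", {"m": [m0]})
        shifted = df.assign(m=df.m - m0)
        refit = smf.ols("y ~ x * m", shifted).fit()
        assert out["slope"].iloc[0] == pytest.approx(refit.params["x"], rel=1e-10)
        assert out["se"].iloc[0] == pytest.approx(refit.bse["x"], rel=1e-10)


def moderated_dataset(four_way=0.9, n_sub=24, n_tr=100, seed=2):
    rng = np.random.default_rng(seed)
    rows = []
    mods = rng.normal(size=n_sub)
    for s in range(n_sub):
        rec = rng.choice([-0.5, 0.5], n_tr)
        eff = rng.normal(size=n_tr)
        mag = rng.normal(size=n_tr)
        mz = mods[s]
        y = 1.0 + 0.3 * eff + four_way * rec * eff * mag * mz + rng.normal(0, 0.5, n_tr)
        y += rng.normal(0, 0.5)
        rows.append(
            pd.DataFrame(
                {
                    "participant": s,
                    "recipient_c": rec,
                    "effort_z": eff,
                    "magnitude_z": mag,
                    "y": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True), {i: m for i, m in enumerate(mods)}


class TestCrossTaskModeration:
    def test_recovers_four_way_sign(self):
        df, mods = moderated_dataset(four_way=0.9)
        coded = CodedDataset(df, "y")
        res, grid = cross_task_moderation(coded, mods, moderator_name="logK_z", re_terms=())
        assert res.coef("recipient_c:effort_z:magnitude_z:logK_z") > 0
        assert res.pvalue("recipient_c:effort_z:magnitude_z:logK_z") < 0.05
        assert len(grid) == 8  # recipient x magnitude x moderator grid

    def test_negated_moderator_flips_interaction(self):
        df, mods = moderated_dataset(four_way=0.9)
        coded = CodedDataset(df, "y")
        res_pos, _ = cross_task_moderation(coded, mods, re_terms=())
        res_neg, _ = cross_task_moderation(
            coded, {k: -v for k, v in mods.items()}, re_terms=()
        )
        a = res_pos.coef("recipient_c:effort_z:magnitude_z:logK_z")
        b = res_neg.coef("recipient_c:effort_z:magnitude_z:logK_z")
        assert a == pytest.approx(-b, rel=1e-6)

    def test_constant_moderator_rejected(self):
        df, mods = moderated_dataset()
        with pytest.raises(ValueError, match="constant"):
            cross_task_moderation(CodedDataset(df, "y"), {k: 1.0 for k in mods})

    def test_too_many_missing_rejected(self):
        df, mods = moderated_dataset()
        for k in list(mods)[: int(0.5 * len(mods))]:
            mods[k] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cross_task_moderation(CodedDataset(df, "y"), mods)


class TestCovariateControl:
    def base(self, seed=3):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(10):
            rec = rng.choice([-0.5, 0.5], 80)
            eff = rng.normal(size=80)
            mag = rng.normal(size=80)
            val = rng.choice([-0.5, 0.5], 80)
            y = 1.0 - 0.6 * rec * eff - 0.5 * rec * eff * mag + rng.normal(0, 0.8, 80)
            rows.append(
                pd.DataFrame(
                    {
                        "participant": s, "recipient_c": rec, "effort_z": eff,
                        "magnitude_z": mag, "valence_c": val, "y": y,
                        "cov": rng.normal(size=80),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def spec(self):
        return ModelSpec("y ~ recipient_c * effort_z * magnitude_z * valence_c")

    def test_uncorrelated_covariate_leaves_keys_unchanged(self):
        coded = CodedDataset(self.base(), "y")
        _, comparison = covariate_control(coded, self.spec(), "cov")
        assert comparison["sign_retained"].all()
        drift = (
            comparison["estimate_controlled"] - comparison["estimate_base"]
        ).abs()
        assert (drift < 0.05).all()

    def test_zero_variance_covariate_rejected(self):
        df = self.base()
        df["cov"] = 2.0
        with pytest.raises(ValueError, match="zero variance"):
            covariate_control(CodedDataset(df, "y"), self.spec(), "cov")

    def test_outcome_copy_rejected(self):
        df = self.base()
        df["cov"] = df["y"]
        with pytest.raises(ValueError, match="duplicates"):
            covariate_control(CodedDataset(df, "y"), self.spec(), "cov")

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            covariate_control(CodedDataset(self.base(), "y"), self.spec(), "nope")


@needs_lme4
class TestLme4Backend:
    def test_gaussian_satterthwaite(self):
        df, betas = generated_dataset(n_sub=8, n_tr=40, resid=0.5, slope_sd=0.4)
        spec = ModelSpec(
            "y ~ x * m", re_terms=("x",), df_method="satterthwaite", backend="lme4"
        )
        res = fit_mixed_model(CodedDataset(df, "y"), spec)
        assert res.backend == "lme4"
        assert np.isfinite(res.table["df"]).all()
        assert res.coef("x") == pytest.approx(betas["x"], abs=0.3)
        sm_res = fit_mixed_model(
            CodedDataset(df, "y"), ModelSpec("y ~ x * m", re_terms=("x",))
        )
        assert res.coef("x") == pytest.approx(sm_res.coef("x"), abs=0.02)

    def test_binomial_wald_z(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(8):
            x = rng.normal(size=80)
            eta = 0.5 + 1.2 * x + rng.normal(0, 0.5)
            ok = rng.random(80) < 1 / (1 + np.exp(-eta))
            rows.append(pd.DataFrame({"participant": s, "x": x, "ok": ok.astype(int)}))
        df = pd.concat(rows, ignore_index=True)
        spec = ModelSpec("ok ~ x", re_terms=(), family="binomial")
        res = fit_mixed_model(CodedDataset(df, "ok"), spec)
        assert res.backend == "lme4"
        assert res.coef("x") > 0 and res.pvalue("x") < 0.01
        assert np.isnan(res.table["df"]).all()  # Wald Z, no df
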
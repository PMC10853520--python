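import math

import numpy as np
import pandas as pd
import pytest

from sketchdev import simulate
from sketchdev.tracing import (
    AffineParams,
    RegistrationOptions,
    fit_tracing_calibration,
    ncc,
    register_affine,
    score_tracings,
    tracing_errors,
    warp_raster,
)


@pytest.fixture(scope="module")
def star_target():
    _, raster = simulate.make_target_shape("star", size=128, extent=0.7)
    return raster


class TestWarpAndNCC:
    def test_identity_warp_is_identity(self, star_target):
        np.testing.assert_allclose(
            warp_raster(star_target, AffineParams.identity()), star_target, atol=1e-9
        )

    def test_warp_then_inverse_round_trips(self, star_target):
        p = AffineParams(tx=6, ty=-4, theta=0.3, sx=1.2, sy=1.2)
        back = warp_raster(warp_raster(star_target, p), p.inverse())
        # interpolation blurs edges; interior and background agree closely
        assert np.mean(np.abs(back - star_target)) < 0.02

    def test_anisotropic_inverse_leaves_family(self):
        with pytest.raises(ValueError):
            AffineParams(sx=2.0, sy=1.0).inverse()

    def test_ncc_bounds_and_degenerate(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert -1 <= ncc(a, b) <= 1
        assert ncc(a, a) == pytest.approx(1.0)
        assert math.isnan(ncc(np.ones((8, 8)), a))


class TestRegistration:
    def test_self_registration_is_identity(self, star_target):
        res = register_affine(star_target, star_target)
        assert res.final_ncc > 0.999
        assert abs(res.params.tx) < 0.5 and abs(res.params.ty) < 0.5
        assert abs(res.params.theta) < math.radians(1)
        assert abs(math.log(res.params.sx)) < 0.02

    def test_translation_recovery(self, star_target):
        true = AffineParams(tx=5, ty=3)
        moved = warp_raster(star_target, true)
        res = register_affine(moved, star_target)
        assert res.final_ncc > 0.99
        assert res.params.tx == pytest.approx(-5, abs=0.5)
        assert res.params.ty == pytest.approx(-3, abs=0.5)

    def test_rotation_recovery(self, star_target):
        true = AffineParams(theta=math.radians(20))
        rotated = warp_raster(star_target, true)
        res = register_affine(rotated, star_target)
        assert abs(res.params.theta + math.radians(20)) < math.radians(1)

    def test_blank_tracing_flagged(self, star_target):
        res = register_affine(np.ones_like(star_target), star_target)
        assert res.blank
        assert math.isnan(res.final_ncc)
        assert res.params == AffineParams.identity()

    def test_constant_target_rejected(self, star_target):
        with pytest.raises(ValueError):
            register_affine(star_target, np.ones_like(star_target))

    def test_stroke_generated_tracing_recovers_transform(self):
        # the stroke-based generator (contour transform + rasterize), not a
        # raster warp: recovery is looser but must find the right transform
        from sketchdev.corpus import rasterize

        true = AffineParams(tx=8, ty=-6, theta=math.radians(12), sx=0.9, sy=0.9)
        trial = simulate.generate_tracing_trial(
            "star", true, contour_noise=0.0, seed=0, size=128
        )
        traced = rasterize(trial.strokes, size=128, canvas_size=(128, 128))
        res = register_affine(traced, trial.target)
        inv = true.inverse()
        assert math.hypot(res.params.tx - inv.tx, res.params.ty - inv.ty) < 1.0
        assert abs(res.params.theta - inv.theta) < math.radians(2)
        assert res.final_ncc > 0.97


class TestTracingErrors:
    def test_identity_gives_zero_errors(self):
        e = tracing_errors(AffineParams.identity(), final_ncc=1.0)
        assert (
            e.shape_error == e.translation_mag == e.rotation_mag == e.scaling_mag == 0.0
        )

    def test_closed_forms(self):
        e = tracing_errors(AffineParams(tx=3, ty=4, theta=-0.3, sx=2.0, sy=1.0), 0.9)
        assert e.translation_mag == pytest.approx(5.0)
        assert e.rotation_mag == pytest.approx(0.3)
        assert e.scaling_mag == pytest.approx(math.log(2))
        assert e.shape_error == pytest.approx(0.1)


def _synthetic_errors(n, seed, sessions=False):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "shape_error": rng.uniform(0, 1.0, n),
            "translation_mag": rng.uniform(0, 30, n),
            "rotation_mag": rng.uniform(0, 0.6, n),
            "scaling_mag": rng.uniform(0, 0.7, n),
            "shape_id": rng.choice(["square", "star"], n),
        },
        index=[f"t{i}" for i in range(n)],
    )
    if sessions:
        df["session_id"] = [f"s{i // 2}" for i in range(n)]
    return df


TRUE_COEF = {
    "shape_error": -2.0,
    "translation_mag": -0.05,
    "rotation_mag": -1.5,
    "scaling_mag": -1.0,
    "shape[star]": 0.4,
}


def _ratings_from(errors, seed, rater_sd=0.5, per=3):
    x = errors.copy()
    x["shape[star]"] = (errors["shape_id"] == "star").astype(float)
    return simulate.generate_ratings(
        x, TRUE_COEF, thresholds=[-3.5, -2.5, -1.5, -0.5],
        rater_sd=rater_sd, seed=seed, ratings_per_tracing=per,
    )


class TestOrdinalCalibration:
    def test_duplicating_rows_leaves_ml_estimates_unchanged(self):
        # exact duplication invariance holds for the maximum-likelihood
        # limit (no rater-intercept shrinkage); under the default ridge
        # penalty the per-rater shrinkage depends on per-rater counts, so
        # invariance there is only approximate
        errors = _synthetic_errors(120, 3)
        ratings = _ratings_from(errors, seed=5, rater_sd=0.0)
        kw = dict(rater_var_init=1e6, estimate_rater_var=False)
        cal1 = fit_tracing_calibration(errors, ratings, **kw)
        cal2 = fit_tracing_calibration(
            errors, pd.concat([ratings, ratings], ignore_index=True), **kw
        )
        np.testing.assert_allclose(cal1.coef, cal2.coef, atol=1e-3)
        np.testing.assert_allclose(cal1.thresholds, cal2.thresholds, atol=1e-3)

    def test_duplicating_rows_approximately_invariant_with_penalty(self):
        errors = _synthetic_errors(120, 3)
        ratings = _ratings_from(errors, seed=5)
        cal1 = fit_tracing_calibration(errors, ratings)
        cal2 = fit_tracing_calibration(
            errors, pd.concat([ratings, ratings], ignore_index=True)
        )
        np.testing.assert_allclose(cal1.coef, cal2.coef, atol=0.15)

    def test_null_errors_give_marginal_thresholds(self):
        # all error predictors at zero: thresholds must reproduce the
        # marginal cumulative rating frequencies through the logistic link
        n = 2000
        errors = _synthetic_errors(n, 4)
        for c in ("shape_error", "translation_mag", "rotation_mag", "scaling_mag"):
            errors[c] = 0.0
        errors["shape_id"] = "square"
        ratings = _ratings_from(errors, seed=6, rater_sd=0.0, per=1)
        cal = fit_tracing_calibration(errors, ratings)
        cum = (
            ratings["rating"].value_counts(normalize=True).sort_index().cumsum()
        )
        from scipy.special import expit

        fitted_cum = expit(cal.thresholds)
        np.testing.assert_allclose(fitted_cum, cum.to_numpy()[:4], atol=0.03)

    def test_matches_statsmodels_ordered_model_without_rater_effects(self):
        # independent cross-check: with no rater heterogeneity the fit must
        # agree with statsmodels' proportional-odds OrderedModel
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        errors = _synthetic_errors(400, 7)
        ratings = _ratings_from(errors, seed=8, rater_sd=0.0, per=2)
        cal = fit_tracing_calibration(errors, ratings)
        x = errors.copy()
        x["shape[star]"] = (x["shape_id"] == "star").astype(float)
        x = x.drop(columns=["shape_id"])
        if "session_id" in x:
            x = x.drop(columns=["session_id"])
        xo = x.loc[ratings["tracing_id"]]
        om = OrderedModel(
            ratings["rating"].to_numpy(), xo.to_numpy(), distr="logit"
        ).fit(method="bfgs", disp=False)
        np.testing.assert_allclose(
            cal.coef.to_numpy(), om.params[: x.shape[1]], atol=0.05
        )

    def test_degenerate_ratings_rejected(self):
        errors = _synthetic_errors(10, 9)
        ratings = pd.DataFrame(
            {"tracing_id": errors.index, "rater_id": "r0", "rating": 3}
        )
        with pytest.raises(ValueError, match="distinct"):
            fit_tracing_calibration(errors, ratings)


@pytest.fixture(scope="module")
def calibration():
    errors = _synthetic_errors(300, 10)
    return fit_tracing_calibration(errors, _ratings_from(errors, seed=11))


class TestScoring:
    def test_perfect_tracing_scores_highest(self, calibration):
        errors = _synthetic_errors(20, 12, sessions=True)
        errors.loc["t0", ["shape_error", "translation_mag", "rotation_mag", "scaling_mag"]] = 0.0
        scores = score_tracings(errors, calibration)
        x = errors.copy()
        x["shape[star]"] = (x["shape_id"] == "star").astype(float)
        per = x[list(calibration.feature_names)].to_numpy() @ calibration.coef.to_numpy()
        assert per[0] == max(per[x["shape_id"] == errors.loc["t0", "shape_id"]])

    def test_session_score_is_mean_of_its_tracings(self, calibration):
        errors = _synthetic_errors(4, 13, sessions=True)
        scores = score_tracings(errors, calibration)
        x = errors.copy()
        x["shape[star]"] = (x["shape_id"] == "star").astype(float)
        eta = x[list(calibration.feature_names)].to_numpy() @ calibration.coef.to_numpy()
        assert scores["s0"] == pytest.approx((eta[0] + eta[1]) / 2)

    def test_shared_skill_correlates_scores_across_shapes(self, calibration):
        # sessions share a latent skill factor driving both shapes' errors:
        # per-shape latent scores must correlate positively across sessions
        rng = np.random.default_rng(14)
        n_sess = 150
        skill = rng.normal(0, 1, n_sess)
        rows = []
        for i in range(n_sess):
            for shape in ("square", "star"):
                bad = 1 / (1 + np.exp(skill[i] + rng.normal(0, 0.7)))
                rows.append(
                    {
                        "session_id": f"s{i}",
                        "shape_id": shape,
                        "shape_error": bad,
                        "translation_mag": 30 * bad * rng.uniform(0.5, 1),
                        "rotation_mag": 0.6 * bad * rng.uniform(0.5, 1),
                        "scaling_mag": 0.7 * bad * rng.uniform(0.5, 1),
                    }
                )
        errors = pd.DataFrame(rows, index=[f"t{i}" for i in range(len(rows))])
        x = errors.copy()
        x["shape[star]"] = (x["shape_id"] == "star").astype(float)
        eta = pd.Series(
            x[list(calibration.feature_names)].to_numpy()
            @ calibration.coef.to_numpy(),
            index=errors.index,
        )
        sq = eta[(errors["shape_id"] == "square").to_numpy()].to_numpy()
        st = eta[(errors["shape_id"] == "star").to_numpy()].to_numpy()
        assert np.corrcoef(sq, st)[0, 1] > 0.3

    def test_empty_session_absent_not_zero(self, calibration):
        errors = _synthetic_errors(4, 15, sessions=True)
        scores = score_tracings(errors, calibration)
        assert "s99" not in scores.index
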
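import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, gammaln

from gsikit.assign import AssignmentResult
from gsikit.mixing import (
    AREA_EAST,
    AREA_WEST,
    HaulObservation,
    MixingConfig,
    aggregate_hauls,
    before_after_comparison,
    compare_models,
    compute_waic,
    fit_mixing_model,
    predict_longitude_profile,
    standardize,
)


class TestStandardize:
    def test_hand_computation(self):
        s = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(s.values, [-1.0, 0.0, 1.0])
        assert s.original_mean == 2.0 and s.original_sd == 1.0

    def test_idempotent_on_standardized_data(self, rng):
        x = rng.normal(0, 1, 50)
        z = standardize(x).values
        z2 = standardize(z).values
        np.testing.assert_allclose(z2, z, atol=1e-12)

    def test_moments(self, rng):
        s = standardize(rng.normal(5, 3, 100))
        assert abs(s.values.mean()) < 1e-10
        assert s.values.std(ddof=1) == pytest.approx(1.0)

    def test_constant_error(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([2.0, 2.0, 2.0])

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            standardize([1.0])


def _meta_row(ind, haul="h1", stage="", length=np.nan, maturity=""):
    return {
        "individual_id": ind,
        "haul_id": haul,
        "period_id": "2014Q2",
        "utm_x": 13.2,
        "life_stage": stage,
        "maturity": maturity,
        "length_cm": length,
        "salinity": 10.0,
        "oxygen": 6.0,
        "temperature": 8.0,
    }


def _assignment(ind, label):
    return AssignmentResult(ind, {}, {}, label, 39)


class TestAggregateHauls:
    def test_counting(self):
        meta = pd.DataFrame([_meta_row(f"f{i}", stage="adult") for i in range(5)])
        labels = ["east", "east", "east", "west", "west"]
        hauls = aggregate_hauls([_assignment(f"f{i}", l) for i, l in enumerate(labels)], meta)
        assert len(hauls) == 1
        assert hauls[0].east_count == 3 and hauls[0].n_fish == 5
        assert hauls[0].area == AREA_EAST  # utm_x 13.2 >= 13.0

    def test_ambiguous_excluded(self):
        meta = pd.DataFrame([_meta_row(f"f{i}", stage="adult") for i in range(5)])
        labels = ["east", "west", "west", "west", "ambiguous"]
        hauls = aggregate_hauls([_assignment(f"f{i}", l) for i, l in enumerate(labels)], meta)
        assert hauls[0].n_fish == 4

    def test_length_rule(self):
        meta = pd.DataFrame(
            [_meta_row("f0", length=18.0), _meta_row("f1", length=35.0)]
        )
        hauls = aggregate_hauls(
            [_assignment("f0", "east"), _assignment("f1", "east")], meta
        )
        stages = {h.life_stage for h in hauls}
        assert stages == {"juvenile", "adult"}

    def test_maturity_overrides_length(self):
        meta = pd.DataFrame([_meta_row("f0", maturity="spawning", length=18.0)])
        hauls = aggregate_hauls([_assignment("f0", "east")], meta)
        assert hauls[0].life_stage == "adult"

    def test_all_unusable_gives_empty(self):
        meta = pd.DataFrame([_meta_row("f0", stage="adult")])
        assert aggregate_hauls([_assignment("f0", "unusable")], meta) == []

    def test_missing_metadata_error(self):
        meta = pd.DataFrame([_meta_row("f0", stage="adult")])
        with pytest.raises(KeyError):
            aggregate_hauls([_assignment("other", "east")], meta)


class TestHaulObservation:
    def test_validation(self):
        with pytest.raises(ValueError, match="east_count"):
            HaulObservation("h", "p", 5, 4, 13.0, AREA_EAST, "adult", 1, 1, 1)
        with pytest.raises(ValueError, match="n_fish"):
            HaulObservation("h", "p", 0, 0, 13.0, AREA_EAST, "adult", 1, 1, 1)
        with pytest.raises(ValueError, match="life stage"):
            HaulObservation("h", "p", 1, 4, 13.0, AREA_EAST, "egg", 1, 1, 1)


def simulate_hauls(
    rng,
    n_hauls=60,
    n_fish=25,
    intercept=0.0,
    beta_sal=0.0,
    transition=None,
    juvenile_transition=None,
    steepness=4.0,
):
    """Direct binomial haul generator (independent of gsikit.simulate)."""
    hauls = []
    lon = rng.uniform(12.0, 14.5, n_hauls)
    sal = rng.normal(10.0, 1.5, n_hauls)
    oxy = rng.normal(6.0, 1.0, n_hauls)
    tmp = rng.normal(8.0, 2.0, n_hauls)
    zsal = (sal - sal.mean()) / sal.std(ddof=1)
    for i in range(n_hauls):
        for stage in ("adult", "juvenile"):
            eta = intercept + beta_sal * zsal[i]
            t = transition if stage == "adult" else (juvenile_transition or transition)
            if t is not None:
                eta += steepness * (lon[i] - t)
            pi = expit(eta)
            y = rng.binomial(n_fish, pi)
            hauls.append(
                HaulObservation(
                    f"h{i}",
                    f"201{i % 4}Q{i % 4 + 1}",
                    int(y),
                    n_fish,
                    float(lon[i]),
                    AREA_WEST if lon[i] < 13.0 else AREA_EAST,
                    stage,
                    float(sal[i]),
                    float(oxy[i]),
                    float(tmp[i]),
                )
            )
    return hauls


@pytest.fixture(scope="module")
def null_fit():
    rng = np.random.default_rng(100)
    hauls = simulate_hauls(rng, n_hauls=100, n_fish=30)
    cfg = MixingConfig(seed=5, n_draws=800)
    return hauls, fit_mixing_model(hauls, "M0", cfg)


class TestFitMixingModel:
    def test_null_intercept_recovered(self, null_fit):
        _, fit = null_fit
        b0 = fit.beta_summary.set_index("term").loc["intercept"]
        assert abs(b0["mean"]) < 0.15
        assert fit.converged

    def test_covariate_effect_recovered(self):
        rng = np.random.default_rng(200)
        hauls = simulate_hauls(rng, n_hauls=100, n_fish=30, beta_sal=1.0)
        fit = fit_mixing_model(hauls, "M0", MixingConfig(seed=6, n_draws=800))
        row = fit.beta_summary.set_index("term").loc["salinity"]
        assert row["q2.5"] < 1.0 < row["q97.5"]
        assert abs(row["mean"] - 1.0) < 0.4

    def test_smoother_recovers_sharp_transition(self):
        rng = np.random.default_rng(300)
        hauls = simulate_hauls(rng, n_hauls=100, n_fish=30, transition=13.2, steepness=8.0)
        fit = fit_mixing_model(hauls, "M3", MixingConfig(seed=7, n_draws=800))
        prof = predict_longitude_profile(fit)
        # within one knot-width of the true transition
        knot_width = 2.5 / 20
        assert prof.crossing_utm_x == pytest.approx(13.2, abs=knot_width)

    def test_pearson_residuals_unit_scale_under_truth(self, null_fit):
        _, fit = null_fit
        r = fit.diagnostics["pearson_residual"]
        assert np.isfinite(r).all()
        assert abs(r.var() - 1.0) < 0.2

    def test_label_symmetry(self, null_fit):
        hauls, fit = null_fit
        flipped = [
            HaulObservation(
                h.haul_id,
                h.period_id,
                h.n_fish - h.east_count,
                h.n_fish,
                h.utm_x,
                h.area,
                h.life_stage,
                h.salinity,
                h.oxygen,
                h.temperature,
            )
            for h in hauls
        ]
        fit2 = fit_mixing_model(flipped, "M0", fit.config)
        # the fitted model mirrors exactly: latent mode negates, the
        # hyperparameter mode is unchanged, pi at the mode maps to 1 - pi
        dz = fit.spec.X.shape[1] + fit.spec.n_hauls
        np.testing.assert_allclose(fit2.mode[:dz], -fit.mode[:dz], atol=1e-6)
        np.testing.assert_allclose(fit2.mode[dz:], fit.mode[dz:], atol=1e-6)
        pi1 = expit(fit.spec.eta(fit.mode, include_u=False))
        pi2 = expit(fit2.spec.eta(fit2.mode, include_u=False))
        np.testing.assert_allclose(pi2, 1.0 - pi1, atol=1e-8)
        # draw-based summaries agree up to Monte-Carlo error
        np.testing.assert_allclose(
            fit2.beta_summary["mean"].to_numpy(),
            -fit.beta_summary["mean"].to_numpy(),
            atol=0.03,
        )

    def test_m1_requires_both_areas(self):
        rng = np.random.default_rng(1)
        hauls = [h for h in simulate_hauls(rng, n_hauls=10) if h.area == AREA_EAST]
        with pytest.raises(ValueError, match="both areas"):
            fit_mixing_model(hauls, "M1")

    def test_m4_requires_both_stages(self):
        rng = np.random.default_rng(1)
        hauls = [h for h in simulate_hauls(rng, n_hauls=10) if h.life_stage == "adult"]
        with pytest.raises(ValueError, match="both life stages"):
            fit_mixing_model(hauls, "M4")

    def test_needs_two_hauls(self):
        rng = np.random.default_rng(1)
        hauls = [h for h in simulate_hauls(rng, n_hauls=5) if h.haul_id == "h0"]
        with pytest.raises(ValueError, match="two hauls"):
            fit_mixing_model(hauls, "M0")

    def test_unknown_model_error(self, null_fit):
        hauls, _ = null_fit
        with pytest.raises(ValueError, match="unknown model"):
            fit_mixing_model(hauls, "M5")


def waic_oracle(ll):
    """Independent WAIC implementation with a streaming (Welford)
    variance accumulator over draws."""
    S, n = ll.shape
    lppd = 0.0
    p_waic = 0.0
    for i in range(n):
        mx = ll[:, i].max()
        lppd += mx + math.log(np.mean(np.exp(ll[:, i] - mx)))
        mean = 0.0
        m2 = 0.0
        for s in range(S):
            delta = ll[s, i] - mean
            mean += delta / (s + 1)
            m2 += delta * (ll[s, i] - mean)
        p_waic += m2 / (S - 1)
    return -2.0 * (lppd - p_waic)


class TestWaic:
    def test_degenerate_posterior_zero_penalty(self, null_fit):
        hauls, fit = null_fit
        import copy

        f2 = copy.copy(fit)
        f2.draws = np.repeat(fit.mode[None, :], 10, axis=0)
        w = compute_waic(f2)
        spec = fit.spec
        eta = spec.eta(fit.mode)
        pi = expit(eta)
        logc = gammaln(spec.n + 1) - gammaln(spec.y + 1) - gammaln(spec.n - spec.y + 1)
        logp = logc + spec.y * np.log(pi) + (spec.n - spec.y) * np.log1p(-pi)
        assert w == pytest.approx(-2.0 * logp.sum(), rel=1e-10)
        assert f2.p_waic == pytest.approx(0.0, abs=1e-12)

    def test_matches_streaming_oracle(self, null_fit):
        _, fit = null_fit
        from gsikit.mixing import _loglik_draws

        ll = _loglik_draws(fit)
        assert compute_waic(fit) == pytest.approx(waic_oracle(ll), abs=1e-8)

    def test_too_few_draws_error(self, null_fit):
        import copy

        _, fit = null_fit
        f2 = copy.copy(fit)
        f2.draws = fit.draws[:1]
        with pytest.raises(ValueError, match="draws"):
            compute_waic(f2)


class TestCompareModels:
    def test_waic_improves_with_generating_covariate(self):
        rng = np.random.default_rng(400)
        hauls = simulate_hauls(rng, n_hauls=80, n_fish=30, transition=13.2)
        table, fits = compare_models(hauls, ("M0", "M3"), MixingConfig(seed=2, n_draws=600))
        assert table.loc[0, "model"] == "M3"
        assert table.loc[table["model"] == "M0", "delta_waic"].iloc[0] > 10

    def test_deterministic(self):
        rng = np.random.default_rng(500)
        hauls = simulate_hauls(rng, n_hauls=30, n_fish=20)
        t1, _ = compare_models(hauls, ("M0", "M2"), MixingConfig(seed=3, n_draws=500))
        t2, _ = compare_models(hauls, ("M0", "M2"), MixingConfig(seed=3, n_draws=500))
        pd.testing.assert_frame_equal(t1, t2)


class TestPredictProfile:
    def test_m3_rejects_life_stage(self):
        rng = np.random.default_rng(600)
        hauls = simulate_hauls(rng, n_hauls=40, transition=13.0)
        fit = fit_mixing_model(hauls, "M3", MixingConfig(seed=1, n_draws=500))
        with pytest.raises(ValueError, match="life-stage"):
            predict_longitude_profile(fit, life_stage="adult")

    def test_m4_requires_life_stage(self):
        rng = np.random.default_rng(600)
        hauls = simulate_hauls(rng, n_hauls=40, transition=13.0, juvenile_transition=13.5)
        fit = fit_mixing_model(hauls, "M4", MixingConfig(seed=1, n_draws=500))
        with pytest.raises(ValueError, match="life_stage"):
            predict_longitude_profile(fit)
        prof = predict_longitude_profile(fit, life_stage="juvenile")
        assert set(prof.curve.columns) == {"utm_x", "median", "q2.5", "q97.5"}

    def test_m0_has_no_profile(self, null_fit):
        _, fit = null_fit
        with pytest.raises(ValueError, match="smoother"):
            predict_longitude_profile(fit)

    def test_band_covers_true_curve(self):
        rng = np.random.default_rng(700)
        hauls = simulate_hauls(rng, n_hauls=100, n_fish=30, transition=13.2, steepness=4.0)
        fit = fit_mixing_model(hauls, "M3", MixingConfig(seed=9, n_draws=800))
        prof = predict_longitude_profile(fit)
        true_pi = expit(4.0 * (prof.curve["utm_x"].to_numpy() - 13.2))
        inside = (prof.curve["q2.5"] <= true_pi) & (true_pi <= prof.curve["q97.5"])
        assert inside.mean() >= 0.9


class TestBeforeAfter:
    def _hauls(self, east_before, n_before, east_after, n_after):
        mk = lambda pid, e, n, h: HaulObservation(
            h, pid, e, n, 13.0, AREA_EAST, "adult", 10, 6, 8
        )
        return [
            mk("2014Q3", east_before, n_before, "h1"),
            mk("2015Q1", east_after, n_after, "h2"),
        ]

    def test_disjoint_wilson_cis(self):
        tab = before_after_comparison(self._hauls(50, 200, 150, 200), "2014Q4")
        t = tab.set_index(["phase", "area"])
        b = t.loc[("before", "all")]
        a = t.loc[("after", "all")]
        assert b["proportion_east"] == pytest.approx(0.25)
        assert a["proportion_east"] == pytest.approx(0.75)

        # closed-form Wilson bounds, written out independently
        def wilson(k, n, z=1.959963984540054):
            p = k / n
            denom = 1 + z**2 / n
            center = (p + z**2 / (2 * n)) / denom
            half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
            return center - half, center + half

        lo, hi = wilson(50, 200)
        assert b["ci_low"] == pytest.approx(lo, abs=1e-9)
        assert b["ci_high"] == pytest.approx(hi, abs=1e-9)
        assert b["ci_high"] < a["ci_low"]

    def test_identical_proportions_overlap(self):
        tab = before_after_comparison(self._hauls(100, 200, 100, 200), "2014Q4")
        t = tab.set_index(["phase", "area"])
        assert t.loc[("before", "all"), "ci_high"] > t.loc[("after", "all"), "ci_low"]

    def test_single_side_error(self):
        hauls = self._hauls(10, 20, 10, 20)
        with pytest.raises(ValueError, match="before and after"):
            before_after_comparison(hauls, "2013Q1")
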
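"""Sampling, screening, logistic fitting, deviance stepwise and evaluation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from sklearn.metrics import log_loss, roc_auc_score
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from conftest import make_categorical, make_continuous
from ozotrend.changemap import CHANGE_LEGEND
from ozotrend.risemodel import (
    EvalReport,
    SampleSpec,
    build_feature_table,
    cochran_n,
    deviance,
    deviance_from_probs,
    district_means,
    evaluate,
    fit_lrm,
    pearson_screen,
    predict_surface,
    stepwise_deviance,
    stratified_sample,
)
from ozotrend.synthgen import SynthConfig, gen_landcover_pair, gen_stepwise_study
from ozotrend.changemap import encode_change
from ozotrend.winmetrics import focal_metrics


class TestCochran:
    @pytest.mark.parametrize(
        "p, e, z, expected",
        [(60.0, 5.0, 1.96, 369), (50.0, 5.0, 1.96, 385), (50.0, 50.0, 1.0, 1)],
    )
    def test_printed_values(self, p, e, z, expected):
        assert cochran_n(SampleSpec(p=p, e=e, z=z)) == expected

    def test_monotonicity_properties(self):
        base = cochran_n(SampleSpec(p=50.0, e=5.0))
        assert cochran_n(SampleSpec(p=50.0, e=10.0)) < base
        for p in (20.0, 35.0, 65.0, 80.0):
            assert cochran_n(SampleSpec(p=p, e=5.0)) <= base

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SampleSpec(p=0.0)
        with pytest.raises(ValueError):
            SampleSpec(e=-1.0)


class TestStratifiedSample:
    @staticmethod
    def change_raster(counts):
        codes = np.concatenate([[code] * n for code, n in counts.items()])
        side = int(np.ceil(np.sqrt(len(codes))))
        arr = np.full(side * side, -1, np.int32)
        arr[: len(codes)] = codes
        return make_categorical(arr.reshape(side, side), legend=dict(CHANGE_LEGEND))

    def test_allocations_sum_to_n(self):
        ch = self.change_raster({1: 120, 3: 77, 10: 33})
        s = stratified_sample(ch, 100, seed=0)
        assert len(s) == 100

    def test_equal_categories_split_evenly(self):
        ch = self.change_raster({1: 50, 3: 50})
        s = stratified_sample(ch, 10, seed=1)
        assert s["CLA"].value_counts().tolist() == [5, 5]

    def test_largest_remainder_hand_case(self):
        ch = self.change_raster({1: 50, 3: 30, 10: 20})
        s = stratified_sample(ch, 10, seed=2)
        counts = s["CLA"].value_counts()
        assert counts["A"] == 5 and counts["F"] == 3 and counts["FA"] == 2

    def test_every_present_category_gets_a_pixel(self):
        ch = self.change_raster({1: 500, 3: 500, 10: 2})
        s = stratified_sample(ch, 20, seed=3)
        assert "FA" in set(s["CLA"])

    def test_seeded_reproducibility_and_disjoint_exclusion(self):
        ch = self.change_raster({1: 200, 3: 200})
        s1 = stratified_sample(ch, 50, seed=9)
        s2 = stratified_sample(ch, 50, seed=9)
        pd.testing.assert_frame_equal(s1, s2)
        taken = np.zeros(ch.codes.shape, bool)
        taken[s1["row"], s1["col"]] = True
        s3 = stratified_sample(ch, 50, seed=10, exclude=taken)
        overlap = set(zip(s1["row"], s1["col"])) & set(zip(s3["row"], s3["col"]))
        assert not overlap

    def test_oversampling_errors(self):
        ch = self.change_raster({1: 10})
        with pytest.raises(ValueError, match="eligible"):
            stratified_sample(ch, 11, seed=0)


class TestPearsonScreen:
    def test_perfect_and_anti_correlation(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(40)
        f = pd.DataFrame({"HET7": d, "CON7": -d, "dGOC": d})
        tab = pearson_screen(f)
        assert tab.loc["HET7", "r"] == pytest.approx(1.0)
        assert tab.loc["CON7", "r"] == pytest.approx(-1.0)
        assert tab.loc["HET7", "stars"] == "***"

    def test_zero_variance_column_is_flagged(self):
        f = pd.DataFrame(
            {"HET7": np.ones(10), "dGOC": np.random.default_rng(1).random(10)}
        )
        tab = pearson_screen(f)
        assert math.isnan(tab.loc["HET7", "r"])
        assert tab.loc["HET7", "stars"] == "zero variance"

    def test_driven_index_is_significantly_positive(self):
        rng = np.random.default_rng(2)
        het = rng.standard_normal(369)
        f = pd.DataFrame(
            {
                "HET7": het,
                "DMG7": -0.6 * het + 0.4 * rng.standard_normal(369),
                "dGOC": 2.0 * het + rng.standard_normal(369),
            }
        )
        tab = pearson_screen(f)
        assert tab.loc["HET7", "r"] > 0 and tab.loc["HET7", "p_value"] < 0.01
        assert tab.loc["DMG7", "r"] < 0


class TestDeviance:
    def test_saturated_fit_is_zero(self):
        y = np.array([0, 1, 1, 0, 1])
        assert deviance_from_probs(y, y.astype(float)) == 0.0

    def test_coin_flip_probabilities(self):
        n = 64
        y = np.random.default_rng(0).integers(0, 2, n)
        assert deviance_from_probs(y, np.full(n, 0.5)) == pytest.approx(
            2 * n * math.log(2)
        )

    def test_matches_independent_log_loss_identity(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 200)
        p = rng.uniform(0.05, 0.95, 200)
        # saturated log-likelihood of binary data is 0, so the deviance is
        # twice the total cross-entropy
        expected = 2 * 200 * log_loss(y, p, labels=[0, 1])
        assert deviance_from_probs(y, p) == pytest.approx(expected, abs=1e-8)

    def test_contradicted_hard_prediction_is_infinite(self):
        assert deviance_from_probs(np.array([1]), np.array([0.0])) == np.inf


def simple_features(n=400, seed=0, b=(1.5, -1.0), eps=0.2):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
    z = eps + b[0] * x1 + b[1] * x2
    y = (rng.random(n) < expit(z)).astype(int)
    return pd.DataFrame({"HET7": x1, "CON7": x2, "label": y})


class TestFitLrm:
    def test_parameter_recovery_within_confidence_intervals(self):
        hits = np.zeros(3)
        n_rep = 40
        for s in range(n_rep):
            f = simple_features(n=800, seed=100 + s)
            fit = fit_lrm(f)
            ci = fit.result_.conf_int()
            truth = {"const": 0.2, "HET7": 1.5, "CON7": -1.0}
            for i, (name, b) in enumerate(truth.items()):
                lo, hi = ci.loc[name]
                hits[i] += lo <= b <= hi
        assert (hits / n_rep >= 0.85).all()

    def test_null_truth_gives_prevalence_probabilities(self):
        rng = np.random.default_rng(3)
        f = pd.DataFrame(
            {
                "HET7": rng.standard_normal(500),
                "label": rng.integers(0, 2, 500),
            }
        )
        fit = fit_lrm(f)
        p = fit.predict_proba(f.drop(columns="label"))[:, 1]
        assert abs(p.mean() - f["label"].mean()) < 0.05
        assert abs(fit.params_["HET7"]) < 0.5

    def test_fitted_deviance_not_worse_than_intercept_only(self):
        f = simple_features(seed=5)
        full = fit_lrm(f)
        y = f["label"].to_numpy()
        p0 = np.full(len(f), y.mean())
        assert full.deviance_ <= deviance_from_probs(y, p0) + 1e-9

    def test_perfect_separation_raises_naming_offender(self):
        y = np.array([0] * 20 + [1] * 20)
        f = pd.DataFrame({"HET7": np.r_[np.zeros(20), np.ones(20)], "label": y})
        with pytest.raises(PerfectSeparationError, match="HET7"):
            fit_lrm(f)

    def test_cla_dummies_use_most_frequent_reference(self):
        rng = np.random.default_rng(4)
        cla = rng.choice(["A", "F", "FA"], size=300, p=[0.6, 0.3, 0.1])
        y = (rng.random(300) < np.where(cla == "FA", 0.8, 0.4)).astype(int)
        f = pd.DataFrame({"CLA": cla, "label": y})
        fit = fit_lrm(f)
        assert fit.cla_reference_ == "A"
        assert "CLA_A" not in fit.params_.index
        assert {"CLA_F", "CLA_FA"} <= set(fit.params_.index)


class TestStepwiseDeviance:
    def test_single_informative_variable_is_found(self):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.standard_normal((n, 5))
        y = (rng.random(n) < expit(1.8 * x[:, 2])).astype(int)
        f = pd.DataFrame(x, columns=["HOM3", "HET5", "HET7", "DMG5", "CON3"])
        f["label"] = y
        fit = stepwise_deviance(f)
        assert fit.variables_ == ["HET7"]
        led = fit.ledger_
        first = led[led["step"] == 1]
        assert first.loc[first["deviance_drop"].idxmax(), "candidate"] == "HET7"

    def test_duplicate_of_included_variable_not_significant(self):
        f = simple_features(seed=7)
        f["HET7_copy"] = f["HET7"]
        fit = stepwise_deviance(f)
        assert "HET7_copy" not in fit.variables_ or "HET7" not in fit.variables_
        dup = fit.ledger_.query("candidate == 'HET7_copy'")
        final_rows = dup[dup["step"] == dup["step"].max()]
        assert not final_rows["significant"].any()

    def test_ledger_drops_match_independent_nested_fits(self):
        f, _ = gen_stepwise_study(n=369, seed=901)
        fit = stepwise_deviance(f)
        for _, row in fit.ledger_.iterrows():
            base_vars = [v for v in row["model"].split(",")[1:]]
            small = fit_lrm(f, base_vars) if base_vars else fit_lrm(f, [])
            big = fit_lrm(f, base_vars + [row["candidate"]])
            drop = deviance(small, f) - deviance(big, f)
            if np.isfinite(row["deviance_drop"]):
                assert drop == pytest.approx(row["deviance_drop"], abs=1e-8)

    def test_no_signal_yields_intercept_only_with_warning(self):
        rng = np.random.default_rng(8)
        f = pd.DataFrame(
            {
                "HET7": rng.standard_normal(60),
                "label": rng.integers(0, 2, 60),
            }
        )
        fit = stepwise_deviance(f, alpha=1e-6)
        assert fit.variables_ == []


class TestEvaluate:
    def test_pcp_fraction_printed_form(self):
        # 247 correct out of 300 -> 82.33%
        y = np.r_[np.ones(247), np.zeros(53)].astype(int)
        p = np.r_[np.full(247, 0.9), np.full(53, 0.9)]
        f = pd.DataFrame({"HET7": p, "label": y})
        fit = fit_lrm(simple_features(seed=9))

        class _Stub:
            variables_ = fit.variables_
            cla_col = "CLA"

            def predict_proba(self, X):
                pr = X["HET7"].to_numpy()
                return np.column_stack([1 - pr, pr])

        rep = evaluate(_Stub(), f)
        assert rep.pcp == pytest.approx(round(100 * 247 / 300, 2), abs=0.005)

    def test_auc_of_separated_scores_is_one(self):
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        from ozotrend.risemodel import _rank_auc

        assert _rank_auc(y, np.r_[np.zeros(10), np.ones(10)]) == 1.0

    def test_auc_matches_sklearn_oracle_with_ties(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 500)
        scores = np.round(rng.random(500), 2)  # heavy ties
        from ozotrend.risemodel import _rank_auc

        assert _rank_auc(y, scores) == pytest.approx(
            roc_auc_score(y, scores), abs=1e-10
        )

    def test_null_scores_give_half_auc(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 2000)
        from ozotrend.risemodel import _rank_auc

        assert _rank_auc(y, rng.random(2000)) == pytest.approx(0.5, abs=0.05)


class TestSurfaces:
    @staticmethod
    def fitted_scene():
        cfg = SynthConfig(n_rows=36, n_cols=36, seed=77)
        enc = encode_change(*gen_landcover_pair(cfg))
        stack = focal_metrics(enc.raster)
        rng = np.random.default_rng(0)
        het = stack.layer("HET7").values
        ok = np.isfinite(het)
        labels = make_categorical(
            (rng.random(het.shape) < expit(het - het[ok].mean())).astype(np.int32),
            nodata=-9,
            legend={0: "no rise", 1: "rise"},
        )
        eligible = np.ones(het.shape, bool)
        for n in stack.names:
            eligible &= stack.layer(n).valid_mask
        samples = stratified_sample(enc.raster, 150, seed=1, eligible_mask=eligible)
        feats = build_feature_table(samples, stack, rise=labels)
        return enc, stack, feats

    def test_surface_probabilities_in_unit_interval(self):
        enc, stack, feats = self.fitted_scene()
        fit = fit_lrm(feats, ["CLA", "HET7"])
        surf = predict_surface(fit, stack, enc.raster)
        vals = surf.values[np.isfinite(surf.values)]
        assert ((vals > 0) & (vals < 1)).all()

    def test_surface_equals_in_sample_prediction_at_sampled_pixel(self):
        enc, stack, feats = self.fitted_scene()
        fit = fit_lrm(feats, ["CLA", "HET7"])
        surf = predict_surface(fit, stack, enc.raster)
        p = fit.predict_proba(feats)[:, 1]
        r, c = int(feats.loc[0, "row"]), int(feats.loc[0, "col"])
        assert surf.values[r, c] == pytest.approx(p[0], abs=1e-12)

    def test_zero_coefficient_model_maps_to_half(self):
        enc, stack, feats = self.fitted_scene()
        fit = fit_lrm(feats, ["HET7"])
        fit.result_.params[:] = 0.0
        fit.params_[:] = 0.0
        surf = predict_surface(fit, stack, enc.raster)
        vals = surf.values[np.isfinite(surf.values)]
        np.testing.assert_allclose(vals, 0.5)

    def test_missing_layer_is_named(self):
        enc, stack, feats = self.fitted_scene()
        fit = fit_lrm(feats, ["HET7"])
        fit.variables_ = ["HET9"]
        with pytest.raises(KeyError, match="HET9"):
            predict_surface(fit, stack, enc.raster)


class TestDistrictMeans:
    def test_constant_surface(self):
        surf = make_continuous(np.full((4, 4), 0.8))
        zones = make_categorical(
            np.repeat([1, 2], 8).reshape(4, 4), legend={1: "D1", 2: "D2"}
        )
        tab = district_means(surf, zones)
        np.testing.assert_allclose(tab["mean_p"], 0.8)

    def test_two_district_hand_means(self):
        surf = make_continuous([[0.2, 0.4, 0.9]])
        zones = make_categorical(np.array([[1, 1, 2]], np.int32), legend={1: "a", 2: "b"})
        tab = district_means(surf, zones).set_index("district")
        assert tab.loc[1, "mean_p"] == pytest.approx(0.3)
        assert tab.loc[2, "mean_p"] == pytest.approx(0.9)

    def test_global_mean_is_pixel_weighted_mean_of_districts(self):
        rng = np.random.default_rng(12)
        surf = make_continuous(rng.random((10, 10)))
        zones = make_categorical(
            (rng.integers(0, 4, (10, 10)) + 1).astype(np.int32),
            legend={i: f"D{i}" for i in range(1, 5)},
        )
        tab = district_means(surf, zones)
        pooled = (tab["mean_p"] * tab["n_pixels"]).sum() / tab["n_pixels"].sum()
        assert pooled == pytest.approx(surf.values.mean())
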
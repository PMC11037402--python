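"""Feature terms, BIC/LASSO model selection, the correction formula and
the illumination F statistic."""

import math

import numpy as np
import pandas as pd
import pytest

from purepupil import lighting
from purepupil.lighting import (
    CorrectionError,
    CorrectionInput,
    CorrectionModel,
    FeatureTerm,
    FULL_TERM_POOL,
    apply_correction,
    build_feature_matrix,
    correct_dataset_loso,
    illumination_f_statistic,
    lasso_finetune,
    predict_parameter,
    stepwise_bic_select,
)


class TestFeatureMatrix:
    def test_unit_inputs(self):
        row = build_feature_matrix([CorrectionInput(1.0, 1.0)])[0]
        assert row.tolist() == [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 1, 0]

    def test_log_terms_at_b_equals_e(self):
        row = build_feature_matrix([CorrectionInput(math.e, 1.0)])[0]
        terms = list(FULL_TERM_POOL)
        assert row[terms.index(FeatureTerm.LOG_B)] == pytest.approx(1.0)
        assert row[terms.index(FeatureTerm.LOG_B2)] == pytest.approx(1.0)
        assert row[terms.index(FeatureTerm.LOGBxLOGE)] == pytest.approx(0.0)

    def test_columns_match_elementwise_recomputation(self):
        rng = np.random.default_rng(3)
        b = rng.uniform(0.5, 9, 40)
        e = rng.uniform(1, 900, 40)
        X = build_feature_matrix(np.column_stack([b, e]))
        oracle = {
            FeatureTerm.B: b, FeatureTerm.E: e,
            FeatureTerm.B2: b**2, FeatureTerm.E2: e**2,
            FeatureTerm.B_INV: 1 / b, FeatureTerm.E_INV: 1 / e,
            FeatureTerm.LOG_B: np.log(b), FeatureTerm.LOG_E: np.log(e),
            FeatureTerm.LOG_B2: np.log(b) ** 2, FeatureTerm.LOG_E2: np.log(e) ** 2,
            FeatureTerm.BxE: b * e, FeatureTerm.LOGBxLOGE: np.log(b) * np.log(e),
        }
        for j, term in enumerate(FULL_TERM_POOL):
            assert np.allclose(X[:, j], oracle[term])

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(CorrectionError):
            CorrectionInput(0.0, 1.0)
        with pytest.raises(CorrectionError):
            build_feature_matrix(np.array([[1.0, -2.0]]))


def _brute_force_bic_ranking(y, inputs, terms):
    """Independent oracle: raw-scale OLS with intercept for every subset."""
    X = build_feature_matrix(inputs, terms)
    n = len(y)
    out = []
    for mask in range(2 ** len(terms)):
        idx = [j for j in range(len(terms)) if mask >> j & 1]
        A = np.column_stack([np.ones(n)] + [X[:, j] for j in idx])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((y - A @ beta) ** 2))
        bic = n * math.log(max(rss, 1e-12) / n) + (len(idx) + 1) * math.log(n)
        out.append((tuple(terms[j] for j in idx), bic))
    out.sort(key=lambda kv: (kv[1], len(kv[0]), tuple(t.name for t in kv[0])))
    return out


class TestStepwiseBic:
    POOL = (FeatureTerm.B, FeatureTerm.LOG_E, FeatureTerm.E_INV, FeatureTerm.BxE)

    def _inputs(self, rng, n):
        return np.column_stack([rng.uniform(2, 8, n), rng.uniform(10, 900, n)])

    def test_recovers_true_log_term(self):
        rng = np.random.default_rng(0)
        inputs = self._inputs(rng, 200)
        y = 2.0 * np.log(inputs[:, 1]) + rng.normal(0, 0.1, 200)
        top_terms, _ = stepwise_bic_select(y, inputs, terms=self.POOL)[0]
        assert FeatureTerm.LOG_E in top_terms

    def test_constant_response_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        inputs = self._inputs(rng, 50)
        with pytest.warns(UserWarning):
            ranked = stepwise_bic_select(np.full(50, 3.3), inputs, terms=self.POOL)
        assert ranked[0][0] == ()

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(2)
        inputs = self._inputs(rng, 60)
        y = 1.5 * inputs[:, 0] + 0.4 * np.log(inputs[:, 1]) + rng.normal(0, 0.3, 60)
        ranked = stepwise_bic_select(y, inputs, terms=self.POOL, top=16)
        oracle = _brute_force_bic_ranking(y, inputs, self.POOL)
        assert [set(s) for s, _ in ranked] == [set(s) for s, _ in oracle]
        assert np.allclose([b for _, b in ranked], [b for _, b in oracle], atol=1e-6)


class TestLassoFinetune:
    POOL = (FeatureTerm.B, FeatureTerm.LOG_E, FeatureTerm.E_INV, FeatureTerm.BxE)

    def _dataset(self, seed, n_subj=6, reps=30, noise=0.05):
        rng = np.random.default_rng(seed)
        n = n_subj * reps
        inputs = np.column_stack([rng.uniform(2, 8, n), rng.uniform(10, 900, n)])
        subjects = np.repeat([f"s{i}" for i in range(n_subj)], reps)
        y = 3.0 * np.log(inputs[:, 1]) + rng.normal(0, noise, n)
        return y, inputs, subjects

    def test_alpha_zero_reduces_to_ols(self):
        y, inputs, subjects = self._dataset(0)
        cand = [(FeatureTerm.B, FeatureTerm.LOG_E)]
        model = lasso_finetune(cand, y, inputs, subjects, alpha=0.0)
        A = np.column_stack([np.ones(len(y)),
                             build_feature_matrix(inputs, cand[0])])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert model.intercept == pytest.approx(beta[0], abs=1e-6)
        coef = [model.coefficients.get(t, 0.0) for t in cand[0]]
        assert np.allclose(coef, beta[1:], atol=1e-6)

    def test_duplicated_column_collapses(self):
        y, inputs, subjects = self._dataset(1)
        cand = [(FeatureTerm.LOG_E, FeatureTerm.LOG_E2, FeatureTerm.LOG_E)]
        model = lasso_finetune(cand, y, inputs, subjects, alpha=0.006)
        assert len(model.terms) == len(set(model.terms))

    def test_recovers_single_true_term_across_replicates(self):
        cands = [(), (FeatureTerm.B,), (FeatureTerm.LOG_E,),
                 (FeatureTerm.B, FeatureTerm.LOG_E),
                 (FeatureTerm.LOG_E, FeatureTerm.E_INV)]
        hits = 0
        for seed in range(20):
            y, inputs, subjects = self._dataset(seed + 100)
            model = lasso_finetune(cands, y, inputs, subjects, alpha=0.006)
            hits += set(model.terms) == {FeatureTerm.LOG_E}
        assert hits >= 18

    def test_average_is_training_grand_mean(self):
        y, inputs, subjects = self._dataset(5)
        model = lasso_finetune([(FeatureTerm.LOG_E,)], y, inputs, subjects)
        assert model.average == pytest.approx(np.mean(y), abs=1e-12)


class TestPredictAndCorrect:
    def test_intercept_only_prediction(self):
        m = CorrectionModel("camp", [], {}, intercept=1.8, average=1.8)
        assert predict_parameter(m, CorrectionInput(3.0, 55.0)) == pytest.approx(1.8)

    def test_single_log_term_prediction(self):
        m = CorrectionModel("camp", [FeatureTerm.LOG_E],
                            {FeatureTerm.LOG_E: 0.5}, intercept=1.0, average=0.0)
        assert predict_parameter(
            m, CorrectionInput(1.0, math.e**2)
        ) == pytest.approx(2.0)

    def test_prediction_equals_manual_dot_product(self):
        terms = [FeatureTerm.B, FeatureTerm.E2, FeatureTerm.LOGBxLOGE]
        coeffs = {terms[0]: 0.31, terms[1]: -2e-4, terms[2]: 0.05}
        m = CorrectionModel("end", terms, coeffs, intercept=-0.7, average=3.0)
        b, e = 4.2, 130.0
        manual = -0.7 + 0.31 * b + -2e-4 * e**2 + 0.05 * math.log(b) * math.log(e)
        assert predict_parameter(m, CorrectionInput(b, e)) == pytest.approx(
            manual, abs=1e-12
        )

    def test_correction_formula(self):
        assert apply_correction(3.5, 3.0, 4.0) == pytest.approx(4.5)
        assert apply_correction(2.0, 2.0, 1.8) == pytest.approx(1.8)

    def test_correction_is_shift_equivariant(self):
        delta = 0.37
        assert apply_correction(3.5 + delta, 3.0, 4.0) - apply_correction(
            3.5, 3.0, 4.0
        ) == pytest.approx(delta, abs=1e-12)

    def test_serialization_round_trip_preserves_predictions(self):
        terms = [FeatureTerm.B, FeatureTerm.LOG_E]
        m = CorrectionModel("mcv", terms,
                            {terms[0]: 0.123456789012345, terms[1]: -7.5e-3},
                            intercept=0.99, average=-4.4,
                            diagnostics={"r2": 0.83})
        m2 = CorrectionModel.from_dict(
            __import__("json").loads(m.to_json())
        )
        probe = np.column_stack([np.linspace(2, 8, 13), np.linspace(5, 900, 13)])
        assert np.array_equal(m.predict(probe), m2.predict(probe))

    def test_unknown_fields_rejected(self):
        d = CorrectionModel("end", [], {}, 0.0, 1.0).to_dict()
        d["bogus"] = 1
        with pytest.raises(CorrectionError):
            CorrectionModel.from_dict(d)


def _loso_frame(seed=0, n_subj=4, reps=12, outlier=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subj):
        sid = f"s{i}"
        for _ in range(reps):
            b = rng.uniform(2.5, 7.5)
            e = rng.uniform(20, 800)
            y = 0.4 * b + 1.2 * np.log(e)
            if outlier is not None and sid == outlier:
                y += 5.0
            rows.append({"subject_id": sid, "illumination": round(e, -1),
                         "baseline": b, "exposure": e, "camp": y})
    return pd.DataFrame(rows)


class TestLosoCorrection:
    def test_perfectly_predictable_parameter_becomes_constant(self):
        df = _loso_frame()
        # penalty-free limit: with the parameter an exact function of (B, E)
        # the correction collapses to the fold average
        out = correct_dataset_loso(df, parameters=("camp",), alpha=0.0, top=30)
        for _, g in out.groupby("subject_id"):
            assert g["camp_c"].std() == pytest.approx(0.0, abs=1e-6)

    def test_row_order_invariance(self):
        df = _loso_frame(seed=1)
        out1 = correct_dataset_loso(df, parameters=("camp",), top=30)
        shuffled = df.sample(frac=1.0, random_state=9)
        out2 = correct_dataset_loso(shuffled, parameters=("camp",), top=30)
        merged = out1.merge(
            out2[["subject_id", "exposure", "camp_c"]],
            on=["subject_id", "exposure"], suffixes=("", "_b"),
        )
        assert np.allclose(merged["camp_c"], merged["camp_c_b"], atol=1e-9)

    def test_outlier_subject_prediction_differs_from_full_fit(self):
        df = _loso_frame(seed=2, outlier="s3")
        loso = correct_dataset_loso(df, parameters=("camp",), top=30)
        models = lighting.fit_correction_models(df, parameters=("camp",), top=30)
        full = lighting.apply_correction_models(models, df)
        mask = df["subject_id"] == "s3"
        assert not np.allclose(
            loso.loc[mask, "camp_c"], full.loc[mask, "camp_c"], atol=1e-3
        )

    def test_between_subject_differences_preserved(self):
        """Two subjects corrected by the same model at the same lighting
        differ by exactly their measured difference."""
        m = CorrectionModel("camp", [FeatureTerm.LOG_E],
                            {FeatureTerm.LOG_E: 0.5}, intercept=1.0, average=2.0)
        e = 120.0
        c1 = apply_correction(1.9, predict_parameter(m, CorrectionInput(4, e)), m.average)
        c2 = apply_correction(1.1, predict_parameter(m, CorrectionInput(4, e)), m.average)
        assert c1 - c2 == pytest.approx(1.9 - 1.1, abs=1e-12)


class TestIlluminationF:
    def _frame(self):
        # 2 subjects x 2 levels x 3 reps, hand-built
        return pd.DataFrame({
            "y": [4.0, 4.2, 4.1, 3.0, 3.1, 2.9,
                  5.0, 5.1, 4.9, 4.0, 3.8, 4.2],
            "illum": ["L1"] * 3 + ["L2"] * 3 + ["L1"] * 3 + ["L2"] * 3,
            "subj": ["a"] * 6 + ["b"] * 6,
        })

    def test_matches_manual_anova_decomposition(self):
        df = self._frame()
        f, d1, d2 = illumination_f_statistic(df.y, df.illum, df.subj)
        # oracle: explicit RSS of the nested OLS fits
        X_full, X_red = [], []
        for il, su in zip(df.illum, df.subj):
            X_full.append([1.0, il == "L2", su == "b"])
            X_red.append([1.0, su == "b"])
        y = df.y.to_numpy()
        rss = {}
        for key, X in (("full", X_full), ("red", X_red)):
            X = np.array(X, dtype=float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss[key] = float(np.sum((y - X @ beta) ** 2))
        f_oracle = ((rss["red"] - rss["full"]) / 1) / (rss["full"] / (12 - 3))
        assert f == pytest.approx(f_oracle, rel=1e-9)
        assert (d1, d2) == (1, 9)

    def test_no_within_subject_variation_gives_zero(self):
        df = pd.DataFrame({
            "y": [4.0] * 6 + [5.0] * 6,
            "illum": (["L1"] * 3 + ["L2"] * 3) * 2,
            "subj": ["a"] * 6 + ["b"] * 6,
        })
        f, _, _ = illumination_f_statistic(df.y, df.illum, df.subj)
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_subject_offsets_are_absorbed(self):
        df = self._frame()
        f0, *_ = illumination_f_statistic(df.y, df.illum, df.subj)
        y2 = df.y + np.where(df.subj == "a", 10.0, -3.0)
        f1, *_ = illumination_f_statistic(y2, df.illum, df.subj)
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_single_level_rejected(self):
        with pytest.raises(CorrectionError):
            illumination_f_statistic([1, 2, 3], ["L"] * 3, ["a", "b", "a"])
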
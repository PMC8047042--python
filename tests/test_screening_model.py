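import numpy as np
import pandas as pd
import pytest

from vocnet import screening_model as sm
from vocnet.feature_assembly import FeatureTable, PREDICTOR_COLUMNS


def numeric_frame(arr, prefix="MPL"):
    """Wrap an array as a frame of canonical numeric predictor columns."""
    cols = ["MPL", "GCC", "MD", "meanBC", "meanHC", "vocab_percentile",
            "combines_words", "complexity_score"][: arr.shape[1]]
    return pd.DataFrame(arr, columns=cols)


class TestSMOTE:
    def test_balanced_input_returned_unchanged(self):
        X = numeric_frame(np.arange(12.0).reshape(6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        X2, y2 = sm.smote_oversample(X, y, sm.SMOTEConfig(), seed=0)
        pd.testing.assert_frame_equal(X2, X)
        assert (y2 == y).all()

    def test_synthetics_lie_on_the_segment(self):
        # two minority points on the diagonal: synthetics must have equal
        # coordinates strictly inside (0, 1) almost surely
        X = numeric_frame(
            np.array([[0.0, 0.0], [1.0, 1.0]] + [[10 + i, -i] for i in range(10)])
        )
        y = np.array([1, 1] + [0] * 10)
        X2, y2 = sm.smote_oversample(X, y, sm.SMOTEConfig(k_neighbors=1), seed=3)
        synth = X2.iloc[12:]
        assert len(synth) == 8  # minority raised to majority count
        np.testing.assert_allclose(synth.iloc[:, 0], synth.iloc[:, 1], atol=1e-12)
        assert ((synth.iloc[:, 0] >= 0) & (synth.iloc[:, 0] <= 1)).all()

    def test_count_contract(self):
        rng = np.random.default_rng(0)
        X = numeric_frame(rng.normal(size=(33, 3)))
        y = np.array([1] * 3 + [0] * 30)
        X2, y2 = sm.smote_oversample(X, y, sm.SMOTEConfig(), seed=1)
        assert (y2 == 1).sum() == 30
        assert (y2 == 0).sum() == 30
        assert len(X2) == 60

    def test_convexity_of_every_synthetic_row(self):
        rng = np.random.default_rng(5)
        X = numeric_frame(rng.normal(size=(40, 4)))
        y = (rng.random(40) < 0.2).astype(int)
        n_min = y.sum()
        assert 2 <= n_min < 20
        X2, y2 = sm.smote_oversample(X, y, sm.SMOTEConfig(), seed=2)
        minority = X[y == 1].to_numpy()
        for _, row in X2.iloc[len(X):].iterrows():
            v = row.to_numpy(dtype=float)
            ok = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    a, b = minority[i], minority[j]
                    denom = b - a
                    with np.errstate(divide="ignore", invalid="ignore"):
                        ts = np.where(denom != 0, (v - a) / denom, np.nan)
                    ts = ts[np.isfinite(ts)]
                    if len(ts) == 0:
                        ok = ok or np.allclose(v, a)
                        continue
                    t = ts[0]
                    if 0 <= t <= 1 and np.allclose(a + t * denom, v, atol=1e-9) and np.allclose(
                        v[denom == 0], a[denom == 0]
                    ):
                        ok = True
                if ok:
                    break
            assert ok, "synthetic row is not a convex combination of two minority rows"

    def test_categoricals_copied_from_anchor(self):
        X = pd.DataFrame(
            {
                "MPL": [0.0, 1.0, 5.0, 6.0, 7.0, 8.0],
                "gender": pd.array([2, 0, 1, 1, 1, 1], dtype=float),
            }
        )
        y = np.array([1, 1, 0, 0, 0, 0])
        X2, _ = sm.smote_oversample(X, y, sm.SMOTEConfig(k_neighbors=1), seed=0)
        assert set(X2["gender"].iloc[6:]) <= {2.0, 0.0}

    def test_single_minority_row_falls_back_to_duplication(self):
        X = numeric_frame(np.arange(10.0).reshape(5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="duplication"):
            X2, y2 = sm.smote_oversample(X, y, sm.SMOTEConfig(), seed=0)
        assert (y2 == 1).sum() == 4
        assert (X2.iloc[5:] == X.iloc[0]).all().all()

    def test_unimputed_numerics_rejected(self):
        X = numeric_frame(np.array([[np.nan, 1.0], [0.0, 2.0], [1.0, 3.0], [2.0, 4.0]]))
        y = np.array([1, 1, 0, 0])
        with pytest.raises(ValueError, match="imputed"):
            sm.smote_oversample(X, y, sm.SMOTEConfig(), seed=0)


def make_table(X: pd.DataFrame, y: np.ndarray) -> FeatureTable:
    """Pad an informative numeric frame out to the canonical 14-column table."""
    from vocnet.feature_assembly import CATEGORICAL_PREDICTORS, NUMERIC_PREDICTORS

    preds = {}
    rng = np.random.default_rng(99)
    for col in NUMERIC_PREDICTORS:
        if col in X:
            preds[col] = X[col].to_numpy()
        elif col == "vocab_percentile":
            preds[col] = rng.uniform(0, 100, size=len(y))
        else:
            preds[col] = rng.normal(size=len(y))
    levels = ["a", "b", "missing"]
    for col in CATEGORICAL_PREDICTORS:
        preds[col] = pd.Categorical(
            rng.choice(["a", "b"], size=len(y)), categories=levels
        )
    table = pd.DataFrame(preds)[list(PREDICTOR_COLUMNS)]
    meta = pd.DataFrame(
        {"child_id": [f"c{i}" for i in range(len(y))], "dataset_id": "toy",
         "age_band": "younger"}
    )
    return FeatureTable(
        predictors=table,
        labels=pd.Series(y, name="outcome_ll"),
        meta=meta,
        category_levels={c: levels for c in CATEGORICAL_PREDICTORS},
    )


def informative_table(n=120, seed=0):
    """Labels are a deterministic threshold on one numeric predictor."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = (x > 0.8).astype(int)
    X = pd.DataFrame({"MPL": x})
    return make_table(X, y)


class TestDropOneImportance:
    CFG = sm.RFConfig(
        ntree=40, n_inner_folds=4, n_inner_repeats=1, n_outer_repeats=1,
        n_training_runs=1,
    )

    def test_perfectly_predictive_feature_ranks_first(self):
        wins = 0
        for seed in (0, 1, 2):
            table = informative_table(seed=seed)
            report = sm.drop_one_importance(
                table.encoded(), table.labels.to_numpy(), self.CFG, sm.SMOTEConfig(),
                seed=seed,
            )
            top = report.table.iloc[0]
            if top["feature"] == "MPL" and top["importance"] > 0:
                wins += 1
        assert wins >= 2

    def test_duplicated_feature_loses_importance_to_unique_one(self):
        table = informative_table(seed=3)
        X = table.encoded()
        X["GCC"] = X["MPL"]  # exact twin of the informative column
        report = sm.drop_one_importance(
            X, table.labels.to_numpy(), self.CFG, sm.SMOTEConfig(), seed=3
        )
        imp = report.table.set_index("feature")["importance"]
        # removal of either twin is compensated by the other
        unique_informative = informative_table(seed=3)
        ref = sm.drop_one_importance(
            unique_informative.encoded(), unique_informative.labels.to_numpy(),
            self.CFG, sm.SMOTEConfig(), seed=3,
        ).table.set_index("feature")["importance"]
        assert imp["MPL"] <= ref["MPL"]
        assert imp["GCC"] <= ref["MPL"]

    def test_pure_noise_importances_near_zero(self):
        rng = np.random.default_rng(11)
        y = (rng.random(120) < 0.3).astype(int)
        table = make_table(pd.DataFrame(index=range(120)), y)
        report = sm.drop_one_importance(
            table.encoded(), y, self.CFG, sm.SMOTEConfig(), seed=11
        )
        assert report.table["importance"].abs().max() < 15.0  # percentage points

    def test_ranks_are_a_permutation(self):
        table = informative_table(seed=5)
        report = sm.drop_one_importance(
            table.encoded(), table.labels.to_numpy(), self.CFG, sm.SMOTEConfig(), seed=5
        )
        assert sorted(report.table["rank"]) == list(range(1, 15))


class TestNestedCV:
    SMALL = sm.RFConfig(
        ntree=25, mtry_grid=(2, 3), n_outer_folds=2, n_outer_repeats=1,
        n_inner_folds=3, n_inner_repeats=1, n_training_runs=2,
        n_selected_features=4,
    )

    def test_every_child_predicted_once_per_repeat_and_run(self):
        table = informative_table(n=80, seed=21)
        fit = sm.nested_cv_fit(table, self.SMALL, seed=1)
        counts = fit.predictions.groupby(["repeat", "run"])["child_id"].nunique()
        assert (counts == 80).all()

    def test_bit_reproducible_given_seed(self):
        table = informative_table(n=80, seed=22)
        f1 = sm.nested_cv_fit(table, self.SMALL, seed=9)
        f2 = sm.nested_cv_fit(table, self.SMALL, seed=9)
        pd.testing.assert_frame_equal(f1.predictions, f2.predictions)
        assert f1.selected_features == f2.selected_features

    def test_no_leakage_audit(self):
        table = informative_table(n=80, seed=23)
        fit = sm.nested_cv_fit(table, self.SMALL, seed=2, audit=True)
        for fold in fit.audit_record["folds"]:
            assert not (fold["inner_rows"] & fold["test_rows"])

    def test_selection_is_identity_when_k_equals_p(self):
        table = informative_table(n=80, seed=24)
        cfg = sm.RFConfig(
            ntree=15, mtry_grid=(3,), n_outer_folds=2, n_outer_repeats=1,
            n_inner_folds=3, n_inner_repeats=1, n_training_runs=1,
            n_selected_features=14,
        )
        fit = sm.nested_cv_fit(table, cfg, seed=3)
        for rec in fit.per_fold:
            assert len(rec["selected"]) == 14

    def test_single_class_rejected(self):
        table = informative_table(n=40, seed=25)
        table.labels[:] = 0
        with pytest.raises(ValueError):
            sm.nested_cv_fit(table, self.SMALL, seed=0)


class TestExternalValidation:
    def test_model_applied_to_its_own_data_matches_resubstitution(self):
        table = informative_table(n=90, seed=31)
        cfg = sm.RFConfig(
            ntree=30, mtry_grid=(2,), n_inner_folds=3, n_inner_repeats=1,
            n_training_runs=1,
        )
        final = sm.train_final_model(table, cfg, seed=4)
        preds = sm.external_validate(final, table)
        rescore = final.predict_scores(table.encoded())
        np.testing.assert_allclose(preds["score"], rescore)

    def test_unseen_levels_collapse_to_missing(self):
        table_a = informative_table(n=90, seed=32)
        cfg = sm.RFConfig(
            ntree=20, mtry_grid=(2,), n_inner_folds=3, n_inner_repeats=1,
            n_training_runs=1,
        )
        final = sm.train_final_model(table_a, cfg, seed=5)
        table_b = informative_table(n=30, seed=33)
        preds_b = table_b.predictors.copy()
        preds_b["race"] = pd.Categorical(
            ["zz"] * 30, categories=["a", "b", "zz", "missing"]
        )
        table_b2 = FeatureTable(
            predictors=preds_b, labels=table_b.labels, meta=table_b.meta,
            category_levels={**table_b.category_levels, "race": ["a", "b", "zz", "missing"]},
        )
        out = sm.external_validate(final, table_b2)
        assert len(out) == 30
        assert set(out["pred"]) <= {0, 1}
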
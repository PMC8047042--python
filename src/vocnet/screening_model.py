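"""Nested cross-validated random-forest screening models.

The modelling procedure, per outer fold of a repeated stratified 3-fold
split:

1. on the outer-training partition only, an inner repeated stratified
   5-fold loop computes **drop-one (drop-column) importance** for every
   predictor — the classification accuracy of the full forest on the raw
   inner held-out fold minus the accuracy of a forest retrained without the
   predictor — with minority oversampling (SMOTE) applied to each inner
   training partition first;
2. the top ``n_selected_features`` (default 7 of 14) predictors by mean
   importance are kept;
3. ``mtry`` (the number of candidate predictors per split) is tuned on the
   selected predictors by inner-CV balanced accuracy, ties to the smaller
   value;
4. ``n_training_runs`` final forests (``ntree`` trees each) are trained on
   the SMOTE-balanced outer-training partition and scored on the untouched
   outer-test partition.

Numeric predictors are imputed by the training partition's median inside
every fold; SMOTE interpolates minority rows in median/MAD-standardised
numeric space and copies categorical codes from the anchor row. Class
threshold on forest votes is 0.5.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import NearestNeighbors

from vocnet.feature_assembly import (
    CATEGORICAL_PREDICTORS,
    NUMERIC_PREDICTORS,
    FeatureTable,
)
from vocnet.io_datasets import SchemaError

__all__ = [
    "RFConfig",
    "SMOTEConfig",
    "ImportanceReport",
    "FitResult",
    "FinalModel",
    "smote_oversample",
    "drop_one_importance",
    "nested_cv_fit",
    "train_final_model",
    "external_validate",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest and cross-validation layout.

    ``full()`` carries the study-scale defaults (3x10 outer, 5x10 inner,
    100 training runs, 500 trees, mtry grid 2..p). ``reduced()`` is the
    documented desk-scale preset (3x2 outer, 5x2 inner, 5 runs, 150 trees)
    and ``fast()`` a smaller preset for multi-seed simulation studies; see
    docs/methods.md for the scaling rationale.
    """

    ntree: int = 500
    mtry_grid: tuple[int, ...] | None = None  # None -> 2..n_selected_features
    n_outer_folds: int = 3
    n_outer_repeats: int = 10
    n_inner_folds: int = 5
    n_inner_repeats: int = 10
    n_training_runs: int = 100
    n_selected_features: int = 7
    importance_kind: str = "drop-one"  # or "permutation"

    def __post_init__(self):
        if self.n_outer_folds < 2 or self.n_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.importance_kind not in ("drop-one", "permutation"):
            raise ValueError(f"unknown importance_kind {self.importance_kind!r}")

    @classmethod
    def full(cls) -> "RFConfig":
        return cls()

    @classmethod
    def reduced(cls) -> "RFConfig":
        return cls(ntree=150, n_outer_repeats=2, n_inner_repeats=2, n_training_runs=5)

    @classmethod
    def fast(cls) -> "RFConfig":
        return cls(
            ntree=60,
            mtry_grid=(2, 4, 7),
            n_outer_repeats=1,
            n_inner_repeats=1,
            n_training_runs=2,
        )


@dataclass(frozen=True)
class SMOTEConfig:
    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority:majority after oversampling

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def _seed_stream(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) % (2**31), *key])


def _int_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _split_columns(X: pd.DataFrame) -> tuple[list[str], list[str]]:
    numeric = [c for c in X.columns if c in NUMERIC_PREDICTORS]
    categorical = [c for c in X.columns if c in CATEGORICAL_PREDICTORS]
    other = [c for c in X.columns if c not in numeric and c not in categorical]
    # columns outside the canonical schema are treated as numeric
    return numeric + other, categorical


def _median_impute(train: pd.DataFrame, *others: pd.DataFrame):
    """Fill numeric NaNs by the training partition's medians (0 if a column
    is entirely missing in training)."""
    numeric, _ = _split_columns(train)
    med = train[numeric].median()
    med = med.fillna(0.0)
    out = [train.copy()]
    out[0][numeric] = out[0][numeric].fillna(med)
    for df in others:
        c = df.copy()
        c[numeric] = c[numeric].fillna(med)
        out.append(c)
    return out if len(out) > 1 else out[0]


def smote_oversample(
    X: pd.DataFrame,
    y: np.ndarray,
    cfg: SMOTEConfig,
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Raise the minority class to ``target_ratio`` x majority by interpolation.

    Numeric columns must be imputed beforehand. Neighbour search runs in
    median/MAD-standardised numeric space over minority rows only; each
    synthetic row sits uniformly on the segment between an anchor minority
    row and one of its ``k_neighbors`` nearest minority neighbours, with
    categorical columns copied verbatim from the anchor. Fewer than two
    minority rows triggers a documented duplication fallback with a warning.
    """
    y = np.asarray(y).astype(int)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    numeric, categorical = _split_columns(X)
    if X[numeric].isna().any().any():
        raise ValueError("numeric predictors must be imputed before SMOTE")

    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise ValueError("SMOTE requires both classes present")
    minority_label = counts.idxmin()
    n_min, n_maj = counts.min(), counts.max()
    n_target = int(round(cfg.target_ratio * n_maj))
    n_new = n_target - n_min
    if n_new <= 0:
        return X.copy(), y.copy()

    rng = np.random.default_rng(_seed_stream(seed, 101))
    minority = X[y == minority_label]
    if n_min < 2:
        warnings.warn(
            "fewer than 2 minority rows; falling back to duplication instead of SMOTE",
            stacklevel=2,
        )
        picks = rng.integers(0, n_min, size=n_new)
        synth = minority.iloc[picks].copy()
    else:
        Z = minority[numeric].to_numpy(dtype=float)
        med = np.median(Z, axis=0)
        mad = np.median(np.abs(Z - med), axis=0)
        mad[mad == 0] = 1.0
        Zs = (Z - med) / mad
        k = min(cfg.k_neighbors, n_min - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Zs)
        _, nbr_idx = nn.kneighbors(Zs)  # first column is the point itself
        anchors = rng.integers(0, n_min, size=n_new)
        nbr_choice = rng.integers(0, k, size=n_new)
        gaps = rng.random(n_new)
        rows = []
        for a, j, u in zip(anchors, nbr_choice, gaps):
            b = nbr_idx[a, j + 1]
            new_num = Z[a] + u * (Z[b] - Z[a])
            row = dict(zip(numeric, new_num))
            for c in categorical:
                row[c] = minority.iloc[a][c]
            rows.append(row)
        synth = pd.DataFrame(rows, columns=X.columns)
    synth.index = pd.RangeIndex(int(X.index.max()) + 1, int(X.index.max()) + 1 + len(synth))
    X_aug = pd.concat([X, synth], axis=0)
    y_aug = np.concatenate([y, np.full(len(synth), minority_label, dtype=int)])
    return X_aug, y_aug


def _forest(ntree: int, mtry: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree,
        max_features=max(1, int(mtry)),
        random_state=int(seed),
        n_jobs=1,
    )


def _accuracy(y_true, y_pred) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


def _balanced_accuracy(y_true, y_pred) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = []
    for cls in (0, 1):
        mask = y_true == cls
        if mask.any():
            out.append(float(np.mean(y_pred[mask] == cls)))
    return float(np.mean(out)) if out else float("nan")


@dataclass
class ImportanceReport:
    """Per-feature drop-one importance in accuracy percentage points.

    ``table`` has columns (feature, importance, rank); ranks are 1..p with
    ties broken alphabetically. ``selection_frequency`` (filled by the
    nested-CV driver) is the fraction of outer folds in which the feature
    made the pruned set.
    """

    table: pd.DataFrame
    selection_frequency: pd.Series | None = None

    def top(self, k: int) -> list[str]:
        return self.table.sort_values("rank")["feature"].head(k).tolist()


def _inner_splits(X, y, cfg: RFConfig, seed: int):
    splitter = RepeatedStratifiedKFold(
        n_splits=cfg.n_inner_folds, n_repeats=cfg.n_inner_repeats, random_state=seed
    )
    return list(splitter.split(np.zeros(len(y)), y))


def drop_one_importance(
    X: pd.DataFrame,
    y: np.ndarray,
    rf_cfg: RFConfig,
    smote_cfg: SMOTEConfig,
    seed: int,
    audit: dict | None = None,
) -> ImportanceReport:
    """Mean held-out accuracy change from retraining without each feature.

    For every inner split: impute by inner-training medians, SMOTE the
    inner-training rows, fit the full forest and one forest per dropped
    column (all at mtry = sqrt(p)), and score plain classification accuracy
    on the raw inner held-out rows. Importances are averaged over splits and
    expressed in percentage points. ``importance_kind="permutation"``
    replaces retraining with within-test column permutation.
    """
    features = list(X.columns)
    if len(features) < 2:
        raise ValueError("importance needs >= 2 features")
    y = np.asarray(y).astype(int)
    mtry = max(2, int(math.sqrt(len(features))))
    totals = {f: 0.0 for f in features}
    splits = _inner_splits(X, y, rf_cfg, _int_seed(_seed_stream(seed, 7)))
    for s, (tr, te) in enumerate(splits):
        X_tr, X_te = _median_impute(X.iloc[tr], X.iloc[te])
        if audit is not None:
            audit.setdefault("rows_seen", set()).update(X.index[tr])
            audit.setdefault("rows_seen", set()).update(X.index[te])
            audit.setdefault("smote_inputs", set()).update(X.index[tr])
            audit.setdefault("eval_rows", set()).update(X.index[te])
        X_bal, y_bal = smote_oversample(
            X_tr, y[tr], smote_cfg, _int_seed(_seed_stream(seed, 11, s))
        )
        rs = _int_seed(_seed_stream(seed, 13, s))
        full = _forest(rf_cfg.ntree, mtry, rs).fit(X_bal, y_bal)
        acc_full = _accuracy(y[te], full.predict(X_te))
        if rf_cfg.importance_kind == "permutation":
            perm_rng = np.random.default_rng(_seed_stream(seed, 17, s))
            for f in features:
                X_perm = X_te.copy()
                X_perm[f] = perm_rng.permutation(X_perm[f].to_numpy())
                totals[f] += acc_full - _accuracy(y[te], full.predict(X_perm))
        else:
            for f in features:
                keep = [c for c in features if c != f]
                sub = _forest(rf_cfg.ntree, max(2, int(math.sqrt(len(keep)))), rs).fit(
                    X_bal[keep], y_bal
                )
                totals[f] += acc_full - _accuracy(y[te], sub.predict(X_te[keep]))
    n_splits = len(splits)
    table = pd.DataFrame(
        {
            "feature": features,
            "importance": [100.0 * totals[f] / n_splits for f in features],
        }
    ).sort_values(["importance", "feature"], ascending=[False, True], kind="mergesort")
    table["rank"] = np.arange(1, len(features) + 1)
    return ImportanceReport(table=table.reset_index(drop=True))


def _tune_mtry(
    X: pd.DataFrame,
    y: np.ndarray,
    rf_cfg: RFConfig,
    smote_cfg: SMOTEConfig,
    seed: int,
    audit: dict | None = None,
) -> int:
    p = X.shape[1]
    grid = rf_cfg.mtry_grid or tuple(range(2, p + 1))
    grid = sorted({min(m, p) for m in grid if m >= 1}) or [max(1, p)]
    if len(grid) == 1:
        return grid[0]
    splits = _inner_splits(X, y, rf_cfg, _int_seed(_seed_stream(seed, 19)))
    best_m, best_score = grid[0], -np.inf
    for m in grid:
        scores = []
        for s, (tr, te) in enumerate(splits):
            if audit is not None:
                audit.setdefault("smote_inputs", set()).update(X.index[tr])
                audit.setdefault("eval_rows", set()).update(X.index[te])
            X_tr, X_te = _median_impute(X.iloc[tr], X.iloc[te])
            X_bal, y_bal = smote_oversample(
                X_tr, y[tr], smote_cfg, _int_seed(_seed_stream(seed, 23, s))
            )
            model = _forest(rf_cfg.ntree, m, _int_seed(_seed_stream(seed, 29, s, m))).fit(
                X_bal, y_bal
            )
            scores.append(_balanced_accuracy(y[te], model.predict(X_te)))
        mean = float(np.mean(scores))
        if mean > best_score + 1e-12:  # strict improvement; ties keep smaller mtry
            best_m, best_score = m, mean
    return best_m


def _row_hashes(X: pd.DataFrame) -> set[str]:
    return {
        hashlib.sha1(row.tobytes()).hexdigest()
        for row in np.ascontiguousarray(X.to_numpy(dtype=float))
    }


@dataclass
class FitResult:
    """Out-of-fold predictions and per-fold selection records.

    ``predictions`` columns: child_id, repeat, fold, run, score, pred, true.
    ``per_fold`` holds, per outer (repeat, fold): the pruned feature list,
    tuned mtry and the outer-test row indices. ``selected_features`` is the
    modal pruned set (top features by selection frequency).
    """

    predictions: pd.DataFrame
    per_fold: list[dict]
    importance: ImportanceReport
    selected_features: list[str]
    audit_record: dict | None = None

    def run_balanced_accuracies(self) -> np.ndarray:
        """One balanced accuracy per (outer repeat, training run), pooling
        out-of-fold predictions over that repeat's folds."""
        vals = []
        for _, grp in self.predictions.groupby(["repeat", "run"], sort=True):
            vals.append(_balanced_accuracy(grp["true"], grp["pred"]))
        return np.asarray(vals)

    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.run_balanced_accuracies()))


def nested_cv_fit(
    table: FeatureTable,
    rf_cfg: RFConfig,
    smote_cfg: SMOTEConfig | None = None,
    seed: int = 0,
    audit: bool = False,
) -> FitResult:
    """Run the full nested-CV pipeline on a feature table.

    Feature selection and mtry tuning see only each outer fold's training
    partition; the outer-test partition is scored untouched. With
    ``audit=True`` the result records row-identity hashes proving the
    separation (see ``FitResult.audit_record``).
    """
    smote_cfg = smote_cfg or SMOTEConfig()
    X = table.encoded()
    y = table.labels.to_numpy().astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    if counts.min() < rf_cfg.n_outer_folds:
        raise ValueError(
            f"minority class has {counts.min()} member(s); cannot stratify "
            f"{rf_cfg.n_outer_folds}-fold outer CV"
        )
    child_ids = table.meta["child_id"].to_numpy()

    outer = RepeatedStratifiedKFold(
        n_splits=rf_cfg.n_outer_folds,
        n_repeats=rf_cfg.n_outer_repeats,
        random_state=_int_seed(_seed_stream(seed, 1)),
    )
    pred_rows = []
    per_fold = []
    audit_entries = [] if audit else None
    imp_tables = []
    for i, (tr, te) in enumerate(outer.split(np.zeros(len(y)), y)):
        repeat, fold = divmod(i, rf_cfg.n_outer_folds)
        X_tr_raw, X_te_raw = X.iloc[tr], X.iloc[te]
        fold_seed = _int_seed(_seed_stream(seed, 3, i))

        inner_audit = {} if audit else None
        report = drop_one_importance(
            X_tr_raw, y[tr], rf_cfg, smote_cfg, fold_seed, audit=inner_audit
        )
        imp_tables.append(report.table.assign(repeat=repeat, fold=fold))
        selected = report.top(min(rf_cfg.n_selected_features, X.shape[1]))
        mtry = _tune_mtry(
            X_tr_raw[selected], y[tr], rf_cfg, smote_cfg, fold_seed, audit=inner_audit
        )

        X_tr, X_te = _median_impute(X_tr_raw[selected], X_te_raw[selected])
        for run in range(rf_cfg.n_training_runs):
            run_seed = _int_seed(_seed_stream(seed, 5, i, run))
            X_bal, y_bal = smote_oversample(X_tr, y[tr], smote_cfg, run_seed)
            model = _forest(rf_cfg.ntree, mtry, run_seed).fit(X_bal, y_bal)
            score = model.predict_proba(X_te)[:, list(model.classes_).index(1)]
            pred = (score >= 0.5).astype(int)
            for j, idx in enumerate(te):
                pred_rows.append(
                    {
                        "child_id": child_ids[idx],
                        "repeat": repeat,
                        "fold": fold,
                        "run": run,
                        "score": float(score[j]),
                        "pred": int(pred[j]),
                        "true": int(y[idx]),
                    }
                )
        per_fold.append(
            {"repeat": repeat, "fold": fold, "selected": selected, "mtry": mtry,
             "test_index": [int(k) for k in te]}
        )
        if audit:
            audit_entries.append(
                {
                    "repeat": repeat,
                    "fold": fold,
                    "test_hashes": _row_hashes(X_te_raw),
                    "inner_rows": set(inner_audit.get("rows_seen", set()))
                    | set(inner_audit.get("smote_inputs", set()))
                    | set(inner_audit.get("eval_rows", set())),
                    "test_rows": set(X.index[te]),
                }
            )

    all_imp = pd.concat(imp_tables, ignore_index=True)
    mean_imp = (
        all_imp.groupby("feature", as_index=False)["importance"]
        .mean()
        .sort_values(["importance", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    mean_imp["rank"] = np.arange(1, len(mean_imp) + 1)
    freq = (
        pd.Series(
            [f for rec in per_fold for f in rec["selected"]], name="feature"
        )
        .value_counts()
        .reindex(mean_imp["feature"], fill_value=0)
        / len(per_fold)
    )
    overall = freq.sort_values(ascending=False, kind="mergesort").head(
        rf_cfg.n_selected_features
    )
    return FitResult(
        predictions=pd.DataFrame(pred_rows),
        per_fold=per_fold,
        importance=ImportanceReport(table=mean_imp, selection_frequency=freq),
        selected_features=overall.index.tolist(),
        audit_record={"folds": audit_entries} if audit else None,
    )


@dataclass
class FinalModel:
    """A single forest trained on one full dataset, for external validation."""

    model: RandomForestClassifier
    selected_features: list[str]
    mtry: int
    medians: pd.Series
    category_levels: dict
    importance: ImportanceReport

    def predict_scores(self, X_encoded: pd.DataFrame) -> np.ndarray:
        Xs = X_encoded[self.selected_features].copy()
        num = [c for c in Xs.columns if c in self.medians.index]
        Xs[num] = Xs[num].fillna(self.medians[num])
        return self.model.predict_proba(Xs)[:, list(self.model.classes_).index(1)]


def train_final_model(
    table: FeatureTable,
    rf_cfg: RFConfig,
    smote_cfg: SMOTEConfig | None = None,
    seed: int = 0,
) -> FinalModel:
    """Feature-select, tune and fit one forest on the entire dataset.

    Used as the source model for cross-dataset (external) validation: inner
    CV on the full dataset picks the pruned feature set and mtry, then a
    single SMOTE-balanced forest is trained on all rows.
    """
    smote_cfg = smote_cfg or SMOTEConfig()
    X = table.encoded()
    y = table.labels.to_numpy().astype(int)
    report = drop_one_importance(X, y, rf_cfg, smote_cfg, _int_seed(_seed_stream(seed, 31)))
    selected = report.top(min(rf_cfg.n_selected_features, X.shape[1]))
    mtry = _tune_mtry(X[selected], y, rf_cfg, smote_cfg, _int_seed(_seed_stream(seed, 37)))
    numeric, _ = _split_columns(X[selected])
    medians = X[selected][numeric].median().fillna(0.0)
    X_fit = _median_impute(X[selected])
    X_bal, y_bal = smote_oversample(X_fit, y, smote_cfg, _int_seed(_seed_stream(seed, 41)))
    model = _forest(rf_cfg.ntree, mtry, _int_seed(_seed_stream(seed, 43))).fit(X_bal, y_bal)
    return FinalModel(
        model=model,
        selected_features=selected,
        mtry=mtry,
        medians=medians,
        category_levels=dict(table.category_levels),
        importance=report,
    )


def external_validate(final: FinalModel, table_b: FeatureTable) -> pd.DataFrame:
    """Score every row of dataset B with a model trained wholly on dataset A.

    B's categorical values are re-encoded onto A's level lists (values
    unseen by A collapse to the "missing" level), so B never influences the
    model. Returns (child_id, score, pred, true).
    """
    mismatched = [
        c
        for c in CATEGORICAL_PREDICTORS
        if set(table_b.category_levels.get(c, [])) - set(final.category_levels.get(c, []))
        and c in final.selected_features
    ]
    preds = table_b.predictors.copy()
    for c in CATEGORICAL_PREDICTORS:
        a_levels = final.category_levels.get(c)
        if a_levels is None:
            raise SchemaError(f"source model lacks category levels for column {c!r}")
        vals = preds[c].astype(object).map(
            lambda v: v if v in a_levels else "missing"
        )
        preds[c] = pd.Categorical(vals, categories=a_levels)
    if mismatched:
        warnings.warn(
            f"unseen category levels collapsed to 'missing' in: {mismatched}", stacklevel=2
        )
    remapped = FeatureTable(
        predictors=preds,
        labels=table_b.labels,
        meta=table_b.meta,
        category_levels={c: list(final.category_levels[c]) for c in CATEGORICAL_PREDICTORS},
    )
    X_b = remapped.encoded()
    missing_cols = [f for f in final.selected_features if f not in X_b.columns]
    if missing_cols:
        raise SchemaError(f"dataset B lacks predictor column(s): {missing_cols}")
    score = final.predict_scores(X_b)
    return pd.DataFrame(
        {
            "child_id": table_b.meta["child_id"].to_numpy(),
            "score": score,
            "pred": (score >= 0.5).astype(int),
            "true": table_b.labels.to_numpy().astype(int),
        }
    )
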
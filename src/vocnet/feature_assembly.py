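"""Assembly of the 14-predictor modelling table.

Predictors are, in fixed column order: the five network measures (meanBC,
MD, meanHC, MPL, GCC), the vocabulary-size percentile, the word-combining
item (0/1), the grammatical-complexity count, and six demographic
categoricals (gender, race, family_history, income, maternal_education,
paternal_education). The binary LL outcome is joined as the label only
after every predictor has been computed, so no predictor can read it.

Missing numeric predictors remain NaN here and are imputed within training
folds by the modelling layer; missing categorical values become an explicit
``"missing"`` level so models see missingness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vocnet.io_datasets import (
    DEMOGRAPHIC_VARIABLES,
    ChildRecord,
    NormsTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NETWORK_PREDICTORS",
    "NUMERIC_PREDICTORS",
    "CATEGORICAL_PREDICTORS",
    "PREDICTOR_COLUMNS",
    "MISSING_CATEGORY",
    "FeatureTable",
    "vocabulary_percentile",
    "encode_grammar",
    "assemble_features",
]

NETWORK_PREDICTORS = ("meanBC", "MD", "meanHC", "MPL", "GCC")
NUMERIC_PREDICTORS = NETWORK_PREDICTORS + (
    "vocab_percentile",
    "combines_words",
    "complexity_score",
)
CATEGORICAL_PREDICTORS = DEMOGRAPHIC_VARIABLES
PREDICTOR_COLUMNS = NUMERIC_PREDICTORS + CATEGORICAL_PREDICTORS
MISSING_CATEGORY = "missing"

_COMBINE_CODES = {"not yet": 0.0, "not_yet": 0.0, "sometimes": 1.0, "often": 1.0}


def vocabulary_percentile(raw_score: int, age_months: int, norms: NormsTable) -> float:
    """Percentile for a raw vocabulary score at an age (floor lookup).

    The raw score is the child's *total* produced checklist words, nouns and
    non-nouns alike, since norms are built on total productive vocabulary.
    """
    return norms.percentile(raw_score, age_months)


def encode_grammar(record: ChildRecord) -> tuple[float, float]:
    """Numeric (combines_words, complexity_score) for one record.

    The combining item maps "not yet" to 0 and "sometimes"/"often" to 1
    (already-numeric 0/1 pass through); the complexity count passes through
    unchanged. Missing values propagate as NaN for downstream within-fold
    imputation. An unrecognised response code raises ValidationError.
    """
    raw = record.combines_words
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        combines = float("nan")
    elif isinstance(raw, str):
        key = raw.strip().casefold()
        if key not in _COMBINE_CODES:
            raise ValidationError(
                f"unrecognised combines_words response {raw!r} for child {record.child_id}"
            )
        combines = _COMBINE_CODES[key]
    elif raw in (0, 1):
        combines = float(raw)
    else:
        raise ValidationError(
            f"unrecognised combines_words value {raw!r} for child {record.child_id}"
        )
    complexity = float("nan") if record.complexity_score is None else float(record.complexity_score)
    if not np.isnan(complexity) and complexity < 0:
        raise ValidationError(f"negative complexity_score for child {record.child_id}")
    return combines, complexity


@dataclass
class FeatureTable:
    """Children x 14 predictors, the binary label, and row metadata.

    ``predictors`` carries the fixed column order; demographic columns are
    pandas Categoricals whose levels always include ``"missing"``.
    ``category_levels`` records each categorical's level list so an
    externally validated table can be re-encoded onto the same codes.
    """

    predictors: pd.DataFrame
    labels: pd.Series
    meta: pd.DataFrame
    category_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        if tuple(self.predictors.columns) != PREDICTOR_COLUMNS:
            raise ValidationError(
                f"predictor columns must be exactly {PREDICTOR_COLUMNS}, "
                f"got {tuple(self.predictors.columns)}"
            )
        if not set(pd.unique(self.labels.dropna())) <= {0, 1}:
            raise ValidationError("labels must be binary 0/1")
        pct = self.predictors["vocab_percentile"].dropna()
        if ((pct < 0) | (pct > 100)).any():
            raise ValidationError("vocab_percentile must lie in [0, 100]")

    @property
    def n(self) -> int:
        return len(self.predictors)

    def encoded(self) -> pd.DataFrame:
        """Predictors as a float frame: categoricals as non-negative integer
        codes (missing level included as its own code), numerics unchanged
        (NaN preserved for within-fold imputation)."""
        out = {}
        for col in NUMERIC_PREDICTORS:
            out[col] = self.predictors[col].astype(float)
        for col in CATEGORICAL_PREDICTORS:
            out[col] = self.predictors[col].cat.codes.astype(float)
        return pd.DataFrame(out, index=self.predictors.index)

    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        df = pd.concat([self.meta, self.predictors, self.labels.rename("outcome_ll")], axis=1)
        df.to_csv(path, index=False)
        if schema_path is not None:
            schema = {
                "numeric": list(NUMERIC_PREDICTORS),
                "categorical": {c: list(v) for c, v in self.category_levels.items()},
            }
            with open(schema_path, "w", encoding="utf-8") as fh:
                json.dump(schema, fh, indent=1)

    @classmethod
    def read_csv(cls, path: str | Path, schema_path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, encoding="utf-8", dtype={"child_id": str})
        with open(schema_path, encoding="utf-8") as fh:
            schema = json.load(fh)
        levels = {c: list(v) for c, v in schema["categorical"].items()}
        preds = {}
        for col in NUMERIC_PREDICTORS:
            preds[col] = df[col].astype(float)
        for col in CATEGORICAL_PREDICTORS:
            vals = df[col].astype(object).where(df[col].notna(), MISSING_CATEGORY)
            preds[col] = pd.Categorical(vals, categories=levels[col])
        meta_cols = [c for c in ("child_id", "dataset_id", "age_band") if c in df.columns]
        return cls(
            predictors=pd.DataFrame(preds),
            labels=df["outcome_ll"].astype(int),
            meta=df[meta_cols].copy(),
            category_levels=levels,
        )


def _categorical(values: pd.Series, levels: list[str] | None) -> pd.Categorical:
    vals = values.astype(object).where(values.notna(), MISSING_CATEGORY)
    vals = vals.map(lambda v: str(v) if v is not None else MISSING_CATEGORY)
    if levels is None:
        observed = sorted(set(vals) - {MISSING_CATEGORY})
        levels = observed + [MISSING_CATEGORY]
    else:
        levels = list(levels)
        if MISSING_CATEGORY not in levels:
            levels = levels + [MISSING_CATEGORY]
        vals = vals.map(lambda v: v if v in levels else MISSING_CATEGORY)
    return pd.Categorical(vals, categories=levels)


def assemble_features(
    records: list[ChildRecord],
    metrics: pd.DataFrame,
    norms: NormsTable,
    category_levels: dict | None = None,
) -> FeatureTable:
    """Join records with their network metrics into a FeatureTable.

    ``metrics`` must contain one row per (child_id, age_months) covering
    every record (as produced by :func:`vocnet.semantic_network.metrics_table`);
    records without metrics raise a hard error listing the child ids.
    Predictors are computed before labels are joined, so no predictor can
    depend on the outcome.
    """
    keyed = metrics.set_index(["child_id", "age_months"])
    if keyed.index.has_duplicates:
        raise ValidationError("metrics table has duplicate (child_id, age_months) rows")
    missing = [
        f"{r.child_id}@{r.age_months}"
        for r in records
        if (r.child_id, r.age_months) not in keyed.index
    ]
    if missing:
        raise ValidationError(f"records without network metrics: {missing}")

    rows = []
    meta_rows = []
    flags = []
    for rec in records:
        m = keyed.loc[(rec.child_id, rec.age_months)]
        combines, complexity = encode_grammar(rec)
        row = {c: float(m[c]) for c in NETWORK_PREDICTORS}
        row["vocab_percentile"] = vocabulary_percentile(
            rec.raw_vocabulary_size, rec.age_months, norms
        )
        row["combines_words"] = combines
        row["complexity_score"] = complexity
        for var in CATEGORICAL_PREDICTORS:
            row[var] = rec.demographics.get(var)
        rows.append(row)
        meta_rows.append(
            {"child_id": rec.child_id, "dataset_id": rec.dataset_id, "age_band": rec.age_band}
        )
        flags.append(str(m.get("quality_flags", "")) if "quality_flags" in m else "")

    raw = pd.DataFrame(rows)
    preds = {c: raw[c].astype(float) for c in NUMERIC_PREDICTORS}
    levels_out = {}
    for var in CATEGORICAL_PREDICTORS:
        cat = _categorical(raw[var], (category_levels or {}).get(var))
        preds[var] = cat
        levels_out[var] = list(cat.categories)
    predictors = pd.DataFrame(preds)[list(PREDICTOR_COLUMNS)]

    for col in NUMERIC_PREDICTORS:
        frac = predictors[col].isna().mean()
        if frac:
            logger.info("predictor %s: %.1f%% missing (fold-wise imputation)", col, 100 * frac)

    labels = pd.Series([int(r.outcome_ll) for r in records], name="outcome_ll")
    meta = pd.DataFrame(meta_rows)
    meta["quality_flags"] = flags
    return FeatureTable(
        predictors=predictors,
        labels=labels,
        meta=meta,
        category_levels=levels_out,
    )
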
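"""Reading, validation and harmonisation of vocabulary-checklist datasets.

A study dataset arrives as two CSV files plus two reference tables:

* a **long checklist** file with one row per (child, age, produced word),
  the natural export shape of item-level parent-report inventories;
* a **wide per-child** file carrying the word-combining item, the
  grammatical-complexity count, six demographic variables and the binary
  low-language (LL) outcome;
* a **semantic-feature lexicon** mapping each noun to its discrete feature
  set (JSON ``{word: [feature, ...]}`` or long CSV ``word,feature``);
* a **norms table** mapping (age in months, raw vocabulary score) to a
  percentile.

Everything is harmonised into :class:`ChildRecord` / :class:`DatasetBundle`,
the in-memory model consumed by the network, feature-assembly and modelling
layers.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ConfigurationError",
    "ValidationError",
    "DEMOGRAPHIC_VARIABLES",
    "DEFAULT_AGE_BAND_MAP",
    "ChildRecord",
    "FeatureNormsLexicon",
    "NormsTable",
    "DatasetBundle",
    "assign_age_band",
    "read_checklist",
    "aggregate_datasets",
    "read_bundle",
    "write_bundle",
    "dataset_summary",
]


class SchemaError(ValueError):
    """An input file is missing required columns or bundles disagree on schema."""


class ConfigurationError(ValueError):
    """A (dataset, age) pair has no age-band mapping, or a config value is invalid."""


class ValidationError(ValueError):
    """A cell value is outside its documented coding."""


#: The six demographic predictors carried through to modelling.
DEMOGRAPHIC_VARIABLES = (
    "gender",
    "race",
    "family_history",
    "income",
    "maternal_education",
    "paternal_education",
)

#: Harmonisation of (dataset_id, age in months) to the two modelling bands.
DEFAULT_AGE_BAND_MAP = {
    ("eirli", 16): "younger",
    ("eirli", 28): "older",
    ("laser", 18): "younger",
    ("laser", 27): "older",
}

AGE_BANDS = ("younger", "older")


def _normalize_word(word: str) -> str:
    return str(word).strip().casefold()


def assign_age_band(
    dataset_id: str,
    age_months: int,
    band_map: Mapping[tuple[str, int], str] | None = None,
) -> str:
    """Map a (dataset, age) pair to the ``younger``/``older`` modelling band.

    The default map covers the four assessment ages of the two cohorts the
    package emulates (16/28 months and 18/27 months). A user-supplied
    ``band_map`` extends or overrides the default; an unmapped pair raises
    :class:`ConfigurationError`.
    """
    mapping = dict(DEFAULT_AGE_BAND_MAP)
    if band_map:
        mapping.update({(str(k[0]).casefold(), int(k[1])): v for k, v in band_map.items()})
    key = (str(dataset_id).casefold(), int(age_months))
    try:
        band = mapping[key]
    except KeyError:
        raise ConfigurationError(
            f"no age-band mapping for dataset {dataset_id!r} at {age_months} months; "
            "supply band_map to cover it"
        ) from None
    if band not in AGE_BANDS:
        raise ConfigurationError(f"band {band!r} is not one of {AGE_BANDS}")
    return band


@dataclass(frozen=True)
class ChildRecord:
    """One child observed at one age band.

    ``combines_words`` keeps the raw checklist response (``"not yet"`` /
    ``"sometimes"`` / ``"often"`` or an already-coded 0/1); numeric coding is
    the job of :func:`vocnet.feature_assembly.encode_grammar`.
    """

    child_id: str
    dataset_id: str
    age_months: int
    age_band: str
    produced_words: frozenset[str]
    combines_words: object = None
    complexity_score: float | None = None
    demographics: Mapping[str, object] = field(default_factory=dict)
    outcome_ll: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "produced_words", frozenset(self.produced_words))
        if self.outcome_ll is not None and self.outcome_ll not in (0, 1):
            raise ValidationError(
                f"outcome_ll must be binary, got {self.outcome_ll!r} for child {self.child_id}"
            )

    @property
    def raw_vocabulary_size(self) -> int:
        """Total produced checklist words (nouns and non-nouns alike)."""
        return len(self.produced_words)


class FeatureNormsLexicon(Mapping):
    """Immutable word -> semantic-feature-set lookup.

    Word identifiers are case-folded and whitespace-trimmed on construction
    and on lookup, so checklist spellings match the norms regardless of
    capitalisation. Every feature set must be non-empty.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        data: dict[str, frozenset[str]] = {}
        for word, feats in mapping.items():
            key = _normalize_word(word)
            if key in data:
                raise SchemaError(f"duplicate lexicon word {key!r}")
            fs = frozenset(str(f) for f in feats)
            if not fs:
                raise SchemaError(f"lexicon word {key!r} has an empty feature set")
            data[key] = fs
        self._data = data

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureNormsLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureNormsLexicon":
        df = pd.read_csv(path, encoding="utf-8")
        missing = {"word", "feature"} - set(df.columns)
        if missing:
            raise SchemaError(f"lexicon CSV missing column(s): {sorted(missing)}")
        grouped = df.groupby("word")["feature"].agg(set)
        return cls(grouped.to_dict())

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({w: sorted(f) for w, f in sorted(self._data.items())}, fh, indent=1)

    def features(self, word: str) -> frozenset[str]:
        return self._data[_normalize_word(word)]

    def __getitem__(self, word: str) -> frozenset[str]:
        return self._data[_normalize_word(word)]

    def __contains__(self, word: object) -> bool:
        return _normalize_word(str(word)) in self._data

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)


class NormsTable:
    """Step-function lookup from (age, raw vocabulary score) to percentile.

    Within each age, the percentile of a raw score is that of the largest
    tabulated raw score not exceeding it (floor lookup); scores below the
    smallest tabulated row take the table's minimum percentile for that age.
    Percentiles must be non-decreasing in raw score within each age.
    """

    COLUMNS = ("age_months", "raw_score", "percentile")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"norms table missing column(s): {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].astype(
            {"age_months": int, "raw_score": int, "percentile": float}
        )
        df = df.sort_values(["age_months", "raw_score"]).reset_index(drop=True)
        if ((df["percentile"] < 0) | (df["percentile"] > 100)).any():
            raise ValidationError("percentiles must lie in [0, 100]")
        for age, grp in df.groupby("age_months"):
            if (grp["percentile"].diff().dropna() < 0).any():
                raise ValidationError(
                    f"percentile not non-decreasing in raw score at age {age}"
                )
            if grp["raw_score"].duplicated().any():
                raise ValidationError(f"duplicate raw_score rows at age {age}")
        self._df = df

    @classmethod
    def read_csv(cls, path: str | Path) -> "NormsTable":
        # round_trip parsing keeps percentiles bit-identical across write/read
        return cls(pd.read_csv(path, encoding="utf-8", float_precision="round_trip"))

    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(path, index=False)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def ages(self) -> frozenset[int]:
        return frozenset(self._df["age_months"].unique().tolist())

    def percentile(self, raw_score: int, age_months: int) -> float:
        if raw_score < 0:
            raise ValidationError(f"raw_score must be >= 0, got {raw_score}")
        sub = self._df[self._df["age_months"] == int(age_months)]
        if sub.empty:
            raise ConfigurationError(f"norms table does not cover age {age_months} months")
        at_or_below = sub[sub["raw_score"] <= raw_score]
        row = at_or_below.iloc[-1] if not at_or_below.empty else sub.iloc[0]
        return float(min(100.0, max(0.0, row["percentile"])))

    def __eq__(self, other) -> bool:
        return isinstance(other, NormsTable) and self._df.equals(other._df)


@dataclass
class DatasetBundle:
    """A cohort's records plus the reference tables needed to model them."""

    records: list[ChildRecord]
    lexicon: FeatureNormsLexicon
    norms: NormsTable
    provenance: str = ""

    def __post_init__(self):
        for rec in self.records:
            if rec.outcome_ll is None:
                raise ValidationError(
                    f"record {rec.child_id!r} has no LL outcome; outcomes are "
                    "required for every modelled record"
                )

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(int(r.outcome_ll) for r in self.records)

    def unknown_words(self, record: ChildRecord) -> frozenset[str]:
        """Produced words absent from the lexicon (non-nouns / unknown items).

        These are excluded from network construction but still count toward
        the raw vocabulary size used for the percentile lookup.
        """
        return frozenset(w for w in record.produced_words if w not in self.lexicon)

    def records_in_band(self, band: str) -> list[ChildRecord]:
        return [r for r in self.records if r.age_band == band]


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing required column(s): {missing}")


def _clean_cell(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        return value if value else None
    return value


CHILD_COLUMNS = ("child_id", "age_months", "combines_words", "complexity_score", "outcome_ll")


def read_checklist(
    words_path: str | Path,
    children_path: str | Path,
    dataset_id: str,
    band_map: Mapping[tuple[str, int], str] | None = None,
) -> list[ChildRecord]:
    """Read the long word file and wide per-child file into ChildRecords.

    ``words_path`` needs columns ``child_id, age_months, word``; duplicated
    (child, age, word) rows are deduplicated with a logged warning.
    ``children_path`` needs ``child_id, age_months, combines_words,
    complexity_score, outcome_ll`` plus the six demographic columns; a child
    may appear once per age. One record is produced per (child_id,
    age_months) pair present in the per-child file; a validation report is
    logged.
    """
    words = pd.read_csv(words_path, encoding="utf-8", dtype={"child_id": str})
    _require_columns(words, ("child_id", "age_months", "word"), f"checklist {words_path}")
    children = pd.read_csv(children_path, encoding="utf-8", dtype={"child_id": str})
    _require_columns(
        children,
        CHILD_COLUMNS + DEMOGRAPHIC_VARIABLES,
        f"per-child table {children_path}",
    )
    extra = set(children.columns) - set(CHILD_COLUMNS) - set(DEMOGRAPHIC_VARIABLES)
    if extra:
        logger.info("per-child table has %d unused column(s): %s", len(extra), sorted(extra))

    words = words.assign(word=words["word"].map(_normalize_word))
    n_before = len(words)
    words = words.drop_duplicates(subset=["child_id", "age_months", "word"])
    n_dup = n_before - len(words)
    if n_dup:
        logger.warning(
            "checklist %s: %d duplicated (child, age, word) row(s) removed", words_path, n_dup
        )

    dup_children = children.duplicated(subset=["child_id", "age_months"])
    if dup_children.any():
        raise SchemaError(
            f"per-child table {children_path} has duplicate (child_id, age_months) rows"
        )

    word_sets = (
        words.groupby(["child_id", "age_months"])["word"].agg(frozenset).to_dict()
    )
    records: list[ChildRecord] = []
    for _, row in children.iterrows():
        child_id = str(row["child_id"])
        age = int(row["age_months"])
        outcome = row["outcome_ll"]
        records.append(
            ChildRecord(
                child_id=child_id,
                dataset_id=str(dataset_id),
                age_months=age,
                age_band=assign_age_band(dataset_id, age, band_map),
                produced_words=word_sets.get((child_id, age), frozenset()),
                combines_words=_clean_cell(row["combines_words"]),
                complexity_score=(
                    None
                    if _clean_cell(row["complexity_score"]) is None
                    else float(row["complexity_score"])
                ),
                demographics={v: _clean_cell(row[v]) for v in DEMOGRAPHIC_VARIABLES},
                outcome_ll=int(outcome) if _clean_cell(outcome) is not None else None,
            )
        )
    logger.info(
        "read %d record(s) from %s (%d word rows, %d duplicates removed)",
        len(records),
        children_path,
        n_before,
        n_dup,
    )
    return records


def _merge_lexicons(lexicons: list[FeatureNormsLexicon]) -> FeatureNormsLexicon:
    merged: dict[str, frozenset[str]] = {}
    for lex in lexicons:
        for word in lex:
            feats = lex.features(word)
            if word in merged and merged[word] != feats:
                raise SchemaError(f"lexicons disagree on feature set for word {word!r}")
            merged[word] = feats
    return FeatureNormsLexicon(merged)


def _merge_norms(norms: list[NormsTable]) -> NormsTable:
    frames = [n.frame for n in norms]
    merged = pd.concat(frames, ignore_index=True).drop_duplicates()
    dup = merged.duplicated(subset=["age_months", "raw_score"], keep=False)
    if dup.any():
        raise SchemaError("norms tables disagree on percentile for a shared (age, raw) row")
    return NormsTable(merged)


def aggregate_datasets(bundles: list[DatasetBundle], band: str) -> DatasetBundle:
    """Concatenate the requested age band across bundles into one dataset.

    Child ids are namespaced by dataset_id when more than one bundle is
    merged, so ids can never collide; the binary LL outcome is carried
    through as a single column regardless of how each cohort defined it.
    """
    if band not in AGE_BANDS:
        raise ConfigurationError(f"band must be one of {AGE_BANDS}, got {band!r}")
    if not bundles:
        raise ValueError("no bundles to aggregate")
    if len(bundles) == 1:
        bundle = bundles[0]
        return DatasetBundle(
            records=bundle.records_in_band(band),
            lexicon=bundle.lexicon,
            norms=bundle.norms,
            provenance=bundle.provenance,
        )
    demo_keys = [
        frozenset(r.demographics.keys()) for b in bundles for r in b.records[:1]
    ]
    if len(set(demo_keys)) > 1:
        raise SchemaError("bundles have disjoint demographic schemas; cannot aggregate")
    records: list[ChildRecord] = []
    for bundle in bundles:
        for rec in bundle.records_in_band(band):
            records.append(replace(rec, child_id=f"{rec.dataset_id}:{rec.child_id}"))
    return DatasetBundle(
        records=records,
        lexicon=_merge_lexicons([b.lexicon for b in bundles]),
        norms=_merge_norms([b.norms for b in bundles]),
        provenance=" + ".join(b.provenance for b in bundles) + f" [{band}]",
    )


# ---------------------------------------------------------------------------
# bundle directory layout: words.csv, children.csv, lexicon.json, norms.csv,
# meta.json ({"dataset_id": ..., "provenance": ...})
# ---------------------------------------------------------------------------

def write_bundle(bundle: DatasetBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    word_rows = [
        {"child_id": r.child_id, "age_months": r.age_months, "word": w}
        for r in bundle.records
        for w in sorted(r.produced_words)
    ]
    pd.DataFrame(word_rows, columns=["child_id", "age_months", "word"]).to_csv(
        directory / "words.csv", index=False
    )
    child_rows = []
    for r in bundle.records:
        row = {
            "child_id": r.child_id,
            "age_months": r.age_months,
            "combines_words": r.combines_words,
            "complexity_score": r.complexity_score,
            "outcome_ll": r.outcome_ll,
        }
        row.update({v: r.demographics.get(v) for v in DEMOGRAPHIC_VARIABLES})
        child_rows.append(row)
    pd.DataFrame(child_rows).to_csv(directory / "children.csv", index=False)
    bundle.lexicon.to_json(directory / "lexicon.json")
    bundle.norms.to_csv(directory / "norms.csv")
    dataset_ids = sorted({r.dataset_id for r in bundle.records})
    meta = {"dataset_id": dataset_ids[0] if len(dataset_ids) == 1 else dataset_ids,
            "provenance": bundle.provenance}
    with open(directory / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def read_bundle(
    directory: str | Path,
    band_map: Mapping[tuple[str, int], str] | None = None,
) -> DatasetBundle:
    directory = Path(directory)
    with open(directory / "meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    dataset_id = meta["dataset_id"]
    if isinstance(dataset_id, list):
        raise SchemaError("cannot re-read an aggregated multi-dataset bundle directory")
    records = read_checklist(
        directory / "words.csv", directory / "children.csv", dataset_id, band_map
    )
    return DatasetBundle(
        records=records,
        lexicon=FeatureNormsLexicon.from_json(directory / "lexicon.json"),
        norms=NormsTable.read_csv(directory / "norms.csv"),
        provenance=meta.get("provenance", ""),
    )


def dataset_summary(bundle: DatasetBundle) -> dict:
    """Counts and LL prevalence (percent, 1 dp, half-up) for reporting."""
    from vocnet.evaluation_report import round_half_up

    n = bundle.n
    pos = bundle.n_positive
    return {
        "n": n,
        "n_positive": pos,
        "prevalence_pct": round_half_up(100.0 * pos / n, 1) if n else float("nan"),
        "bands": {b: len(bundle.records_in_band(b)) for b in AGE_BANDS},
        "provenance": bundle.provenance,
    }
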
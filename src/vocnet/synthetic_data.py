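"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates parent-report vocabulary-checklist studies of
toddlers followed to a later binary low-language (LL) outcome: a rare
positive class (4-14% prevalence), a few hundred children per age band, a
noun lexicon with semantic-feature norms, word-combining and
grammatical-complexity items driven by vocabulary size, and demographic
categoricals with realistic missingness.

Group signal enters through two separately switchable channels:

* **size** — LL children draw smaller vocabularies (per-group lognormal);
* **structure** — LL children preferentially sample low-connectivity nouns
  (sampling weight proportional to ``(1 + degree)^-structure_bias`` where
  degree is the word's connectivity in the lexicon overlap graph), which
  depresses clustering, degree and harmonic centrality beyond what size
  alone predicts.

With ``structure_bias = 0`` and identical size distributions the two groups
are exchangeable, giving an exact null. The norms table is built from the
generated TD children's empirical raw-score distribution (mid-rank
percentiles), so percentile lookups are self-consistent by construction.

Effect-size defaults are arbitrary calibrations (no field values exist for
them); see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from vocnet.io_datasets import (
    ChildRecord,
    ConfigurationError,
    DatasetBundle,
    FeatureNormsLexicon,
    NormsTable,
    assign_age_band,
)
from vocnet.semantic_network import build_network

__all__ = [
    "DemographicSpec",
    "GrammarSpec",
    "SimConfig",
    "preset",
    "example_lexicon",
    "generate_lexicon",
    "generate_children",
    "shuffle_labels",
]

# Stream offsets: one independent PRNG per logical component, so
# regenerating one component never perturbs the others.
_STREAM_LEXICON = 11
_STREAM_OUTCOME = 23
_STREAM_VOCAB = 37
_STREAM_DEMOGRAPHICS = 53
_STREAM_GRAMMAR = 71
_STREAM_SHUFFLE = 89


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass(frozen=True)
class DemographicSpec:
    """Per-variable category levels, probabilities and missingness rate."""

    levels: tuple[str, ...]
    probs: tuple[float, ...]
    missing_rate: float = 0.0

    def __post_init__(self):
        if len(self.levels) != len(self.probs):
            raise ConfigurationError("levels and probs must have equal length")
        if not math.isclose(sum(self.probs), 1.0, abs_tol=1e-9):
            raise ConfigurationError("category probabilities must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")


def _default_demographics() -> dict[str, DemographicSpec]:
    edu = ("high_school", "some_college", "bachelors", "graduate")
    return {
        "gender": DemographicSpec(("F", "M"), (0.5, 0.5), 0.01),
        "race": DemographicSpec(
            ("white", "black", "asian", "multiracial_other"),
            (0.6, 0.15, 0.1, 0.15),
            0.05,
        ),
        "family_history": DemographicSpec(("no", "yes"), (0.78, 0.22), 0.06),
        "income": DemographicSpec(
            ("lt_35k", "35_75k", "75_125k", "gt_125k"), (0.15, 0.35, 0.3, 0.2), 0.08
        ),
        "maternal_education": DemographicSpec(edu, (0.15, 0.3, 0.35, 0.2), 0.03),
        "paternal_education": DemographicSpec(edu, (0.2, 0.3, 0.3, 0.2), 0.07),
    }


@dataclass(frozen=True)
class GrammarSpec:
    """Logistic links from vocabulary size to the two grammar items.

    ``P(combines) = sigmoid((size - combine_midpoint)/combine_scale)``; the
    complexity count is Binomial(``complexity_items``, sigmoid((size -
    complexity_midpoint)/complexity_scale)). Midpoints are in produced-word
    counts.
    """

    combine_midpoint: float = 25.0
    combine_scale: float = 10.0
    complexity_items: int = 37
    complexity_midpoint: float = 80.0
    complexity_scale: float = 30.0
    missing_rate_combine: float = 0.03
    missing_rate_complexity: float = 0.10


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic age-band dataset.

    Defaults mirror the headline cohort the package emulates: n = 391
    children with LL prevalence 0.043 assessed at 16 months. Vocabulary
    sizes are lognormal per group, parameterised as (mean of log, sd of
    log) and truncated to [1, checklist size].
    """

    n_children: int = 391
    prevalence: float = 0.043
    dataset_id: str = "eirli"
    age_months: int = 16
    lexicon_size: int = 160
    n_semantic_features: int = 50
    features_per_word: tuple[int, int] = (3, 7)
    n_non_nouns: int = 40
    vocab_lognorm_td: tuple[float, float] = (math.log(60.0), 0.55)
    vocab_lognorm_ll: tuple[float, float] = (math.log(30.0), 0.55)
    structure_bias: float = 1.5
    demographic_spec: dict[str, DemographicSpec] = field(default_factory=_default_demographics)
    grammar_spec: GrammarSpec = field(default_factory=GrammarSpec)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        lo, hi = self.features_per_word
        if not 1 <= lo <= hi <= self.n_semantic_features:
            raise ConfigurationError(
                "features_per_word range must satisfy 1 <= lo <= hi <= n_semantic_features"
            )
        if self.lexicon_size < 1:
            raise ConfigurationError("lexicon_size must be >= 1")


_PRESETS = {
    # (dataset, band) -> (n, n_positive, age_months)
    ("eirli", "younger"): (314, 11, 16),
    ("eirli", "older"): (390, 16, 28),
    ("laser", "younger"): (85, 12, 18),
    ("laser", "older"): (85, 12, 27),
}


def preset(dataset: str, band: str = "younger", seed: int = 0, **overrides) -> SimConfig:
    """Named study conditions for the two emulated cohorts x two age bands.

    Sample sizes and positive counts follow the cohorts' reported per-band
    compositions (314/11 and 390/16 for the larger school-age-outcome
    cohort; 85/12 for the smaller direct-assessment cohort). Older bands
    shift the vocabulary-size distributions upward.
    """
    key = (dataset.casefold(), band)
    if key not in _PRESETS:
        raise ConfigurationError(f"unknown preset {dataset!r}/{band!r}")
    n, n_pos, age = _PRESETS[key]
    cfg = SimConfig(
        n_children=n,
        prevalence=n_pos / n,
        dataset_id=dataset.casefold(),
        age_months=age,
        seed=seed,
    )
    if band == "older":
        cfg = replace(
            cfg,
            vocab_lognorm_td=(math.log(110.0), 0.35),
            vocab_lognorm_ll=(math.log(65.0), 0.45),
        )
    return replace(cfg, **overrides) if overrides else cfg


def example_lexicon() -> FeatureNormsLexicon:
    """A four-noun lexicon whose two-shared-feature network has five links.

    Constructed by hand so that every noun pair except (apple, balloon)
    shares exactly two features: the resulting network is the standard
    small worked example used throughout the docs and tests (MPL 7/6,
    mean-local clustering 5/6, mean degree 2.5).
    """
    return FeatureNormsLexicon(
        {
            "apple": ["round", "red", "holdable", "food"],
            "eye": ["round", "red", "body", "small", "paired", "wet"],
            "ball": ["holdable", "food", "body", "small", "toy", "bouncy"],
            "balloon": ["paired", "wet", "toy", "bouncy"],
        }
    )


def generate_lexicon(
    lexicon_size: int,
    n_semantic_features: int,
    features_per_word: tuple[int, int],
    seed: int = 0,
) -> FeatureNormsLexicon:
    """Draw a noun lexicon with a skewed feature-frequency distribution.

    Feature popularity follows a Zipf-like ``1/rank`` law and each word
    samples its feature count uniformly from ``features_per_word`` without
    replacement, so a minority of broadly-shared features creates hub words
    with many two-feature overlaps, as in real feature-norm sets.
    """
    lo, hi = features_per_word
    if not 1 <= lo <= hi <= n_semantic_features:
        raise ConfigurationError("infeasible features_per_word for n_semantic_features")
    rng = _rng(seed, _STREAM_LEXICON)
    feature_ids = [f"f{i:03d}" for i in range(n_semantic_features)]
    weights = 1.0 / np.arange(1, n_semantic_features + 1)
    weights /= weights.sum()
    mapping = {}
    for w in range(lexicon_size):
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(n_semantic_features, size=k, replace=False, p=weights)
        mapping[f"noun{w:03d}"] = [feature_ids[i] for i in chosen]
    return FeatureNormsLexicon(mapping)


def _word_connectivity(lexicon: FeatureNormsLexicon, min_shared: int = 2) -> dict[str, int]:
    net = build_network(list(lexicon), lexicon, min_shared=min_shared)
    g = net.to_networkx()
    return {w: int(g.degree[w]) for w in lexicon}


def _truncated_lognormal(rng, mean_log, sd_log, size, upper):
    draws = np.exp(rng.normal(mean_log, sd_log, size=size))
    return np.clip(np.round(draws), 1, upper).astype(int)


def _empirical_norms(td_sizes: np.ndarray, age_months: int) -> NormsTable:
    """Mid-rank empirical percentiles of the TD raw-score distribution."""
    td_sizes = np.asarray(td_sizes)
    n = len(td_sizes)
    rows = []
    for raw in np.unique(td_sizes):
        below = np.sum(td_sizes < raw)
        at = np.sum(td_sizes == raw)
        pct = 100.0 * (below + 0.5 * at) / n
        rows.append({"age_months": age_months, "raw_score": int(raw), "percentile": pct})
    if rows and rows[0]["raw_score"] > 0:
        rows.insert(0, {"age_months": age_months, "raw_score": 0, "percentile": 0.0})
    return NormsTable(pd.DataFrame(rows))


def generate_children(cfg: SimConfig, lexicon: FeatureNormsLexicon | None = None) -> DatasetBundle:
    """Generate one synthetic age-band dataset under ``cfg``.

    Each child receives an outcome (Bernoulli at the configured prevalence),
    a vocabulary size from the group's lognormal, produced words sampled
    with the group's connectivity weighting, grammar items via the logistic
    links, and demographics with missingness. The returned bundle carries a
    norms table built from the TD children of this very dataset.
    """
    if lexicon is None:
        lexicon = generate_lexicon(
            cfg.lexicon_size, cfg.n_semantic_features, cfg.features_per_word, cfg.seed
        )
    nouns = sorted(lexicon)
    non_nouns = [f"item{i:03d}" for i in range(cfg.n_non_nouns)]
    checklist = nouns + non_nouns
    n_items = len(checklist)

    connectivity = _word_connectivity(lexicon)
    # popularity: Zipf over a seed-determined ordering of the checklist
    order_rng = _rng(cfg.seed, _STREAM_LEXICON + 1)
    order = order_rng.permutation(n_items)
    rank = np.empty(n_items, dtype=int)
    rank[order] = np.arange(n_items)
    popularity = 1.0 / (1.0 + rank)

    degree_arr = np.array([connectivity.get(w, 0) for w in checklist], dtype=float)
    w_td = popularity.copy()
    w_ll = popularity * np.power(1.0 + degree_arr, -cfg.structure_bias)

    out_rng = _rng(cfg.seed, _STREAM_OUTCOME)
    vocab_rng = _rng(cfg.seed, _STREAM_VOCAB)
    demo_rng = _rng(cfg.seed, _STREAM_DEMOGRAPHICS)
    gram_rng = _rng(cfg.seed, _STREAM_GRAMMAR)

    outcomes = (out_rng.random(cfg.n_children) < cfg.prevalence).astype(int)
    sizes = np.where(
        outcomes == 1,
        _truncated_lognormal(vocab_rng, *cfg.vocab_lognorm_ll, cfg.n_children, n_items),
        _truncated_lognormal(vocab_rng, *cfg.vocab_lognorm_td, cfg.n_children, n_items),
    )

    gs = cfg.grammar_spec
    records: list[ChildRecord] = []
    for i in range(cfg.n_children):
        weights = w_ll if outcomes[i] else w_td
        p = weights / weights.sum()
        idx = vocab_rng.choice(n_items, size=int(sizes[i]), replace=False, p=p)
        produced = frozenset(checklist[j] for j in idx)

        size = len(produced)
        p_comb = 1.0 / (1.0 + math.exp(-(size - gs.combine_midpoint) / gs.combine_scale))
        if gram_rng.random() < gs.missing_rate_combine:
            combines = None
        elif gram_rng.random() < p_comb:
            combines = "often" if gram_rng.random() < 0.5 else "sometimes"
        else:
            combines = "not yet"
        p_item = 1.0 / (1.0 + math.exp(-(size - gs.complexity_midpoint) / gs.complexity_scale))
        complexity = (
            None
            if gram_rng.random() < gs.missing_rate_complexity
            else float(gram_rng.binomial(gs.complexity_items, p_item))
        )

        demographics = {}
        for var, spec in cfg.demographic_spec.items():
            if demo_rng.random() < spec.missing_rate:
                demographics[var] = None
            else:
                demographics[var] = str(demo_rng.choice(spec.levels, p=spec.probs))

        records.append(
            ChildRecord(
                child_id=f"{cfg.dataset_id}{i:04d}",
                dataset_id=cfg.dataset_id,
                age_months=cfg.age_months,
                age_band=assign_age_band(cfg.dataset_id, cfg.age_months),
                produced_words=produced,
                combines_words=combines,
                complexity_score=complexity,
                demographics=demographics,
                outcome_ll=int(outcomes[i]),
            )
        )

    td_sizes = sizes[outcomes == 0]
    norms = _empirical_norms(td_sizes if td_sizes.size else sizes, cfg.age_months)
    return DatasetBundle(
        records=records,
        lexicon=lexicon,
        norms=norms,
        provenance=(
            f"synthetic:{cfg.dataset_id}:{cfg.age_months}mo:"
            f"n={cfg.n_children}:seed={cfg.seed}"
        ),
    )


def shuffle_labels(bundle: DatasetBundle, seed: int) -> DatasetBundle:
    """Permute LL outcomes uniformly at random; predictors untouched.

    The multiset of labels (hence prevalence) is preserved exactly; used to
    build the chance-level null the classification pipeline is tested
    against.
    """
    rng = _rng(seed, _STREAM_SHUFFLE)
    labels = [r.outcome_ll for r in bundle.records]
    perm = rng.permutation(len(labels))
    new_records = [
        replace(rec, outcome_ll=labels[perm[i]]) for i, rec in enumerate(bundle.records)
    ]
    return DatasetBundle(
        records=new_records,
        lexicon=bundle.lexicon,
        norms=bundle.norms,
        provenance=bundle.provenance + f":shuffled(seed={seed})",
    )
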
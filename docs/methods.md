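# Methods

## The problem

Persistent language disorder is hard to identify in toddlerhood: most late
talkers catch up, outcome prevalence is low (roughly 4–14% in the cohorts
this package emulates), and simple vocabulary size is a weak early marker.
`vocnet` implements a screening pipeline that augments vocabulary size with
*structural* properties of a child's early lexicon: the organisation of
their produced nouns in semantic-feature space.

## Noun-feature networks

For each child, nodes are the produced nouns that appear in a
semantic-feature lexicon; an undirected edge joins two nouns sharing at
least `min_shared = 2` discrete features. Five summaries are computed:

- **MPL** — mean shortest-path length over *connected* node pairs. Pairs in
  different components are excluded; a network with no connected pair
  returns 0 and carries a quality flag rather than a missing value.
- **GCC** — mean of per-node local clustering coefficients, with nodes of
  degree < 2 contributing 0. The mean-local definition is the one
  consistent with the standard four-node worked example (it gives 5/6 ≈
  0.83 there, where the transitivity ratio gives 0.75); transitivity is
  available behind `variant="transitivity"`.
- **MD** — mean degree, `2|E|/n`.
- **mean BC** — unnormalized betweenness: per node, the sum over unordered
  pairs of other nodes of the fraction of shortest paths through it;
  endpoints excluded, fractional credit across tied shortest paths. A
  normalization switch (divide by `(n-1)(n-2)/2`) exists but is off by
  default; no published value constrains the choice, and the unnormalized
  scale keeps the measure comparable to hand counts on small examples.
- **mean HC** — harmonic centrality: the sum of reciprocal distances to the
  other `n-1` nodes, divided by `n-1`, averaged over nodes. The
  sum-of-inverses form (not inverse-of-sum, which is closeness) is the only
  one with the advertised properties: a 0–1 range and graceful handling of
  unreachable nodes, which matter because sparse late-talker networks are
  often disconnected.

Empty and singleton networks return all-zero metrics plus a quality flag,
so the downstream model always receives numbers; the flag is retained in
the feature-table metadata.

The four-noun example lexicon (`synthetic_data.example_lexicon`) was
constructed by hand to realise the five-edge worked-example network from
overlap constraints: every noun pair shares exactly two features except
(apple, balloon), which shares none.

## The 14-predictor table

Predictors, in fixed order: the five network measures; the vocabulary-size
percentile (step-function floor lookup of *total* produced words — nouns
and non-nouns — in an age × raw-score norms table, since norms are built on
total productive vocabulary); the word-combining item (not yet → 0,
sometimes/often → 1); the grammatical-complexity count; and six demographic
categoricals (gender, race, family history of speech/language disorder,
income, maternal and paternal education).

Missing handling: categoricals carry an explicit `"missing"` level —
missingness itself may be informative and real checklist data have plenty —
while numeric predictors stay NaN until they are imputed by the *training
partition's* median inside every cross-validation fold, which avoids
test-set leakage through the imputation statistics. Categoricals enter the
forest as integer codes: forests split on thresholds, so codes work without
dummy expansion, at the cost of imposing an arbitrary order within
unordered variables; with `ntree` in the hundreds this has little practical
effect and mirrors common forest practice.

## Modelling procedure

Repeated stratified nested cross-validation around a random-forest
classifier:

- **Outer loop** (3 folds × `n_outer_repeats`): estimates generalization.
  Stratification is required — at 4.3% prevalence an unstratified 3-fold
  split can easily produce a single-class fold.
- **Inner loop** (5 folds × `n_inner_repeats`, on the outer-training
  partition only): computes drop-one feature importance, prunes to the top
  7 of 14 features, and tunes `mtry` (candidate features per split) over a
  grid from 2 to the number of kept features.
- **Final models**: `n_training_runs` forests of `ntree` trees per outer
  fold, each trained on the SMOTE-balanced outer-training partition and
  scored on the untouched outer-test partition; votes ≥ 0.5 predict the
  positive class.

**Drop-one importance** is retraining importance as such: accuracy of the
full forest on the raw (unbalanced) inner held-out fold minus the accuracy
of a forest retrained without the feature, averaged over inner splits and
expressed in percentage points; ties in the ranking break alphabetically. A
permutation-importance option is provided for comparison but is not the
default. Plain accuracy is used here; `mtry` tuning instead maximises
*balanced* accuracy (ties to the smaller `mtry`), which is better defined
under residual imbalance in the held-out folds. Importance forests use
`mtry = sqrt(p)`, and SMOTE is applied once per inner split on the full
feature set (dropped columns are removed afterwards), which keeps the
full-vs-reduced comparison on identical training rows. Note a structural
caveat: drop-one importance of strongly correlated features is near zero
(each is compensated by the others), so a *set* of redundant informative
features can individually rank low — the selection-frequency report exists
partly for this reason.

**SMOTE** raises the minority class to a 1:1 ratio with the majority by
interpolation: numeric columns are standardised by median/MAD (MAD 0 → 1)
for the nearest-neighbour search among minority rows (`k = 5`, capped at
minority−1), each synthetic row sits uniformly on the segment between an
anchor and one of its neighbours in the original units, and categorical
codes are copied from the anchor. Fewer than two minority rows triggers a
duplication fallback with a warning, never silently. SMOTE sees only
training partitions, at every level of the nesting.

**External validation** retrains a single model on all of dataset A
(selection and tuning by inner CV on A alone) and scores every row of
dataset B; B's categorical values are re-encoded onto A's levels, unseen
levels collapsing to `"missing"`. Ensembling the outer-CV models would be a
reasonable alternative; the single retrained model is simpler and uses all
of A's rows.

### Scale presets

`RFConfig.full()` is the study-scale layout: 3×10 outer, 5×10 inner, 100
training runs, 500 trees. The package's own analyses and tests use smaller
presets, chosen as the sizes at which the qualitative conclusions
(chance-level behaviour under label shuffling, recovery of injected
effects) are already stable:

- `RFConfig.reduced()` — 3×2 outer, 5×2 inner, 5 runs, 150 trees; used for
  single-dataset demonstrations and the shuffled-label null.
- `RFConfig.fast()` — 3×1 outer, 5×1 inner, 2 runs, 60 trees, `mtry` grid
  {2,4,7}; used for multi-seed simulation studies where the outer
  replication across seeds substitutes for within-fit repetition.

## Evaluation

Confusion matrices (positive class = LL) feed sensitivity, specificity,
balanced accuracy `(sens+spec)/2`, PPV/NPV, and the likelihood ratios
`LR+ = sens/(1−spec)`, `LR− = (1−sens)/spec`. Conventions at the edges:
perfect specificity gives LR+ = +∞ (serialized `"Inf"`); zero specificity
gives LR− = +∞; PPV/NPV with an empty denominator are *missing*, never 0.
Balanced accuracies per (outer repeat, training run) — pooling that
repeat's folds — feed a one-sided one-sample t-test against the 0.5
chance baseline; exactly constant inputs return an explicit degenerate
result instead of a p-value. Report tables round half-up at 2 decimals
(so 0.99/0.18 prints 5.50); machine-readable output keeps full precision.

## The synthetic generator

`synthetic_data` emulates the structure of the two cohorts the pipeline
was designed around: presets with (n, positives, age) of (314, 11, 16 mo)
and (390, 16, 28 mo) for the larger school-age-outcome cohort and
(85, 12, 18/27 mo) for the smaller direct-assessment cohort, with an
aggregate-style default of n = 391 at prevalence 0.043.

Per child: outcome ~ Bernoulli(prevalence); vocabulary size from a
per-group truncated lognormal; produced words drawn without replacement
from a 200-item checklist (160 lexicon nouns + 40 non-noun items) with
weight ∝ popularity × (1 + connectivity)^(−`structure_bias`) for LL
children and ∝ popularity for TD, where connectivity is the word's degree
in the lexicon's own overlap graph. Grammar items follow logistic links
from vocabulary size; demographics are independent categoricals with
5–10% missingness. One PRNG stream per component (lexicon, outcomes,
vocabularies, demographics, grammar), each seeded from the master seed
plus a fixed offset.

The two effect channels (size, structure) can be switched independently:
equal size distributions with `structure_bias = 0` give exact
exchangeability (the null used by the shuffled-label and KS tests). The
norms table is the TD children's own mid-rank empirical percentile
function, so the TD median lands at the 50th percentile by construction.

Default effect sizes — TD log-mean vocabulary 60 vs LL 30 at the younger
band, `structure_bias = 1.5` — are **arbitrary calibrations**: no
quantitative group effects for the network measures are published, so the
defaults are set where parameter-recovery simulations separate the groups
clearly, and they should not be read as empirical estimates. The
parameter-recovery study conditions (n = 400, prevalence 0.10,
`structure_bias` 1.2, LL log-mean 35, grammar links flattened so the
injected signal is confined to the network measures and the percentile)
are defined in `tests/conftest.py:recovery_config`.

What the generator does *not* emulate: psycholinguistic realism of the
lexicon (feature norms are licensed datasets), longitudinal growth within
a child, correlated demographics, and demographic–outcome associations.
Passing tests therefore show that the pipeline recovers the kinds of
signal it assumes, not that real cohorts carry that signal.

## Numerical and design notes

- Word identifiers are case-folded and trimmed before lexicon lookup.
- Percentile lookup is a floor step function, clamped to [0, 100]; raw
  scores below the smallest tabulated row take the age's minimum
  percentile.
- Age bands are a fixed map over (dataset, age-in-months) pairs; children
  contributing records at both bands are treated as independent rows of the
  two band datasets.
- Determinism: every stochastic component (generator, fold splitter,
  SMOTE, forests) is seeded through a `SeedSequence` tree from a single
  master seed; the full pipeline is bit-reproducible on a fixed platform.
- The betweenness and shortest-path computations are delegated to
  networkx; the test suite cross-checks them (and the hand-rolled pieces)
  against an independent brute-force BFS/path-enumeration oracle on 200
  random graphs to 1e−9.

## Known limitations

- Drop-one importance under correlated predictors (above) is conservative;
  selection frequency across folds is the more stable readout.
- The categorical integer coding imposes an order on unordered variables.
- SMOTE treats categoricals by anchor-copying, which under-disperses
  synthetic minority rows in the categorical dimensions.
- With prevalence near 4% and 3 outer folds, per-fold test partitions
  contain only a handful of positives; per-run balanced accuracies are
  correspondingly noisy, which is why they are pooled within repeats
  before the t-test.
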
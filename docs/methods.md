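# Methods

## Scope and data model

The package explains binary risk predictions on tabular patient-period
instances. An *item* is a feature-value pair: an equality condition on a
categorical feature, or membership in a half-open interval for a binned
continuous feature. A *class association rule* is a conjunction of items
(one feature at most once per rule) predicting the poor-outcome class. Rules
carry raw counts; confidence `C_r = n_matched_positive / n_matched` and
commonality `S_r = n_matched_positive / n_positive_total` are derived from
the counts at access time, so stored fractions can never drift from the
arithmetic. Percentages are produced only at display time (two decimals).

A missing feature value satisfies no condition. This is the conservative
reading — rules never fire on unobserved data — and it interacts with
discretization (below): missing values are excluded from cut fitting and
remain missing after binning. If "missing" is informative for a feature, an
explicit missing category should be created upstream as an ordinary level.

## Supervised discretization

Continuous features are binned per feature, independently, by recursive
binary splitting on the training set. At each node the candidate cut (a
midpoint between adjacent distinct sorted values) maximizing information
gain is found; the split is accepted iff

    gain > [log2(N−1) + log2(3^k − 2) − k·Ent(S) + k1·Ent(S1) + k2·Ent(S2)] / N

with `N` the node size, `k`, `k1`, `k2` the class counts of the node and its
halves — the Fayyad–Irani MDL stopping criterion, the canonical
entropy-based discretizer for this setting. Gain ties (within 1e-12) go to
the smallest cut value, making the fit deterministic. Bins are
left-open/right-closed `(low, high]`, with end bins `(−inf, c_1]` and
`(c_last, +inf)`; a value equal to a cut therefore falls in the lower bin,
and the bin index is non-decreasing in the raw value. A feature whose labels
carry no exploitable signal gets zero cuts; its single whole-line bin only
asserts that the value is not missing, so the miner drops such items (as it
drops any item matching every row).

With a rare outcome (~1.5% positive), node entropy is small (~0.12 bits) and
only genuinely outcome-shifted features pay the MDL coding cost; in the
default synthetic cohort exactly the three planted signal features receive
cuts and the twelve noise features receive none.

## Constrained rule mining

Only rules predicting the poor outcome are mined, under three inclusive
thresholds: commonality ≥ 1%, confidence ≥ 50%, at most 5 LHS items. Since
commonality is support within the positive class, it is anti-monotone over
positive instances: the miner runs a level-wise Apriori search restricted to
positive rows with support floor `min_commonality`, then computes each
frequent itemset's confidence against the full table and keeps those at or
above the confidence floor. Items from the same feature are never combined —
under mutually exclusive bins and levels such a conjunction is either
redundant or empty. Rule files are written in a canonical order (confidence
desc, commonality desc, lexicographic item keys) so that mining is
reproducible byte-for-byte; the per-patient ranking happens later and does
not depend on file order.

Mining uses the full training table (all instances, not just those above the
prediction cutoff): commonality's denominator is the count of all training
positives. A brute-force subset enumerator with identical filters, plus a
second fully independent row-scanning enumerator in the test suite, serve as
oracles; the miner must agree with both exactly (rules and counts) on every
fixture.

Threshold comparisons use an absolute epsilon of 1e-9 below the configured
floor, so a rule at exactly the boundary (confidence 0.50) is retained while
0.009 commonality against a 0.01 floor is dropped.

## Explanation and intervention linking

For a patient flagged by the upstream classifier, every rule whose LHS the
patient satisfies is an explanation; the set may be empty. Explanations are
defined only for predicted poor outcomes and the API refuses other patients.
An intervention catalog maps item keys to clinician-precompiled texts; an
item with at least one text is *actionable*, a rule is actionable iff any of
its items is. Texts reachable from several items of one rule are listed once
(first occurrence, LHS order). Catalogs are validated against the rule set's
item universe at load time so that a stale catalog (e.g., interval keys from
an older discretization) fails loudly instead of silently making everything
nonactionable.

## Ranking

Per patient, each rule's score is a five-term linear combination:

    score_r = w_c·norm(C_r) + w_s·norm(log10 S_r) − w_n·norm(N_r)
              + w_d·mean_i exp(−d·t_i) + w_a·δ_actionable(r)

Parameter semantics and defaults:

| parameter | role | default |
|---|---|---|
| `w_c` | weight of normalized confidence | 1 |
| `w_s` | weight of normalized log10 commonality | 1 |
| `w_n` | weight of normalized LHS length (subtracted) | 1 |
| `w_d` | weight of the diversity (decay) term | 50 |
| `w_a` | actionable-rule bonus | 100 |
| `d` | decay constant of `exp(−d·t)` | 5 |
| `w_g` | item novelty weight (item score) | 1 |
| `w_b` | actionable-item bonus (item score) | 2 |
| `n` | rules displayed initially | 3 |

Commonality is log-transformed before normalization because rule commonality
distributions are heavily right-skewed; the min–max normalization then
absorbs any multiplicative rescaling of commonality (fraction vs percent) as
an additive log constant, so scores are scale-invariant. The normalizer is
computed once over the patient's full initial pool of `q` rules and frozen
for the whole ranking; consequently the only iteration-dependent term is the
diversity mean, and the greedy step need only rescore rules sharing an item
with the previously ranked rule. This incremental update is exactly
equivalent to rescoring everything (property-tested against a full-rescan
reference over random pools, weights and seeds, with exact score equality).

With `w_a > w_c + w_s + w_n + w_d` every actionable rule outscores every
nonactionable rule at every iteration, because the four other terms each lie
in [0, 1] (the three normalized terms and the decay mean); the value of
`w_a` shifts actionable scores by a constant and cannot reorder them.
`w_b > w_g` gives the same dominance for items within a rule. Under default
weights every score lies in [−1, 152].

Randomness: one seeded generator per ranking call drives all tie-breaks,
consumed in a fixed order — rule-score ties first (uniform choice among the
tied rules, index-sorted), then item-score ties of the newly ranked rule
(shuffle within each equal-score group, groups in descending score). The
generator is consumed only when a genuine tie (exact float equality) occurs,
so adding unrelated rules cannot perturb unrelated tie-breaks. Identical
inputs and seed give identical output. The score attached to each ranked
rule is its selection-time score, i.e. the quantity the greedy step
maximized; item usage counts `t` for item sorting reflect the top `k−1`
rules, not the rule being displayed.

`select_top` returns the first `min(n, q)` rules with an offset/limit for
pagination; a display-count threshold is used rather than a score threshold
because score distributions differ per patient.

## Risk-score coupling

Any classifier that produces a risk score per instance can sit upstream.
Scores are binarized by flagging exactly `floor(fraction·N)` instances in
descending score order (default fraction 0.10); boundary ties resolve by
stable input order, which makes the flagged count exact and the operation
reproducible. Confusion metrics (sensitivity, specificity, PPV, NPV,
accuracy) are reported as percentages; a metric with a zero denominator is
`None`, never 0. The bundled reference classifier — a logistic regression on
one-hot encoded discretized features — exists so demos and tests have a
score column; its discrimination is not a claim of this package.

## Synthetic cohorts

The generator emulates the *shape* of an administrative/clinical feature
table: 30 features (15 continuous, 10 categorical with 8 background levels,
5 binary at rate 0.3), n = 20,000 patient-period instances, poor-outcome
prevalence 1.5% (within the 1.5–1.7% range typical of asthma hospital
encounter cohorts), 2% missingness on continuous features, and index years
2011–2018 supporting a train-on-past / test-on-2018 temporal split. Three
continuous features are outcome-shifted (by 1.0, 0.8 and 0.5 SD) to give the
discretizer real signal.

Planted rules are injected at the item level on dedicated categorical levels
that never occur in the background distribution: for a rule with target
commonality `s` and confidence `c`, `round(s·n_pos)` positive rows and
`round(s·n_pos/c) − round(s·n_pos)` negative rows receive the rule's items.
Realized quality therefore deviates from targets only through integer
rounding and overlap between rules sharing items; ground truth reports the
realized counts from a final scan. Planting is deliberately *not* done in
discretized-bin space: tying ground-truth counts to fitted cut points would
make the recovery targets circular. Planted levels are unique per feature
and no planted item set may be a subset of another (either would corrupt the
count targeting; both are validated before sampling). The default planted
set is overlap-heavy — three rules share one item, a fourth shares items
with two of them — which is exactly the redundancy the diversity term
exists to penalize, plus one rule below the confidence floor and one below
the commonality floor that mining must *not* recover.

What the cohorts do not emulate: feature correlation structure, informative
missingness, temporal drift between index years, label noise, and planted
patterns on continuous features. Passing tests therefore demonstrate the
correctness of the algorithms under known ground truth, not clinical
performance on real EHR data.

## Sensitivity protocol

One parameter among `w_c`, `w_s`, `w_n`, `w_d`, `d` is varied over a grid
with the others at their defaults (`w_a`, `w_g`, `w_b` are excluded: they
only separate actionable from nonactionable entries without affecting order
within each group). For every eligible patient — predicted positive with
q ≥ 1 — the unique items in the top `min(3, q)` rules are compared between
the default and the modified configuration under the same seed, so only the
parameter change, never tie-break noise, drives the metric. "Change" is the
fraction of baseline top items absent from the variant top set, normalized
by the baseline set size, which keeps the metric in [0, 100]; a
symmetric-difference mode is available as a switch. Two aggregations are
computed: the mean of per-patient percentages (default) and the pooled
numerator-over-denominator ratio. On the default synthetic cohort the
protocol reproduces the characteristic signature of this scoring function:
the change is exactly 0 at each parameter's default and stays small across
default-adjacent values, while disabling diversity entirely (`d = 0` or
`w_d = 0`) produces a far larger shift in the displayed items.

## Pipeline, problem sizes, determinism

`run_end_to_end` chains generate/load → temporal split → discretize (train
only) → mine → score and binarize (test) → explain predicted positives →
rank → write artifacts. Every stage writes a reloadable artifact
(discretization map, rules JSON, catalog, scored test CSV, ranked
explanations JSON, metrics, report), making the pipeline resumable at any
stage boundary, and the whole run is byte-deterministic given the config
seed. The split is temporal when an index-period column is present
(mirroring a train-on-2011–2017 / test-on-2018 design) and a seeded random
fraction otherwise.

Problem sizes used by the shipped tests and the acceptance script, chosen to
exercise every code path at desk scale: mining-recovery and sensitivity
checks run on the full n = 20,000 default cohort; pipeline-determinism and
demo runs use n = 4,000 at 5% prevalence with a 5% commonality floor (the
1% floor at 200 positives admits itemsets covering two or three positive
rows, which inflates the lattice without testing anything further); oracle
equivalence suites use 1,000 random rule pools (q ≤ 50), 100 random tiny
tables, and 200 random vectors (n ≤ 50).

## Known limitations

- Interval catalog keys must match the mined bins exactly; re-discretizing
  invalidates a catalog (by design, loudly).
- Joint-item interventions (one text tied to a *combination* of items) are
  approximated by per-item linking with de-duplication.
- The miner materializes one boolean vector per frequent itemset over the
  positive rows; with very dense item distributions and the 1% floor this
  lattice can grow large. The defaults keep it in the tens of thousands of
  itemsets; pathological inputs (many near-universal items) should raise the
  commonality floor.
- Only binary outcomes are supported; multiclass labels are out of scope for
  both the discretizer and the miner.
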
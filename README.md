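# rulerank

Rule-based explanation — and, centrally, explanation *ranking* — for
black-box binary risk predictions on tabular clinical data.

## The problem

Risk models used to enroll patients into care management (for example,
predicting which patients with asthma will have an inpatient stay or
emergency-department visit in the next 12 months) are usually black boxes.
A practical way to explain an individual high-risk prediction is through
*class association rules* mined from the training data: conjunctions of
feature-value pair items, such as

> ≥13 ED visits in the past year AND ≥4 systemic corticosteroid
> prescriptions in the past year → hospital encounter in the next 12 months,

each annotated with clinician-precompiled interventions. Every rule a
patient satisfies is a candidate explanation of their predicted poor
outcome. The catch: a typical high-risk patient satisfies many rules, and
the top of an unordered list is redundant and hard to act on. This package
implements the full pipeline — supervised discretization, constrained rule
mining, explanation retrieval with intervention linking — around its core: a
scoring function and iterative procedure that rank a patient's rules so the
top few are precise, common, short, *diverse* and *actionable*.

## The ranking method

For each rule `r: p_1 AND … AND p_m → v` found for one patient, with
confidence `C_r` (precision of the rule), commonality `S_r` (fraction of all
poor-outcome instances it covers) and LHS length `N_r`:

```
score_r = w_c·norm(C_r) + w_s·norm(log10 S_r) − w_n·norm(N_r)
          + w_d·mean_i exp(−d·t_i) + w_a·δ_actionable(r)
```

`norm()` is min–max normalization over the patient's `q` rules (0 when all
values are equal), fixed once per patient. `t_i` counts how often item `p_i`
appears in already-ranked rules, so the exponential-decay term penalizes
redundancy; ranking is greedy, rescoring at step `k` only rules that share
an item with the `(k−1)`-th pick, which provably equals full rescoring.
Score ties are broken randomly under a caller-supplied seed. Defaults:
`w_c = w_s = w_n = 1`, `w_d = 50`, `w_a = 100`, `d = 5`. Because
`w_a > w_c + w_s + w_n + w_d`, actionable rules always outrank
nonactionable ones. Items inside each displayed rule are sorted by
`score_p = w_g·exp(−d·t) + w_b·δ_actionable(p)` with `w_g = 1`, `w_b = 2`,
and the top `n = 3` rules are displayed by default.

The surrounding stages follow the same design: continuous features are
binned by recursive entropy minimization with the Fayyad–Irani MDL stopping
criterion; mining keeps exactly the rules with commonality ≥ 1%,
confidence ≥ 50% and at most 5 items, found Apriori-style over the
positive-class instances (commonality is anti-monotone there); any external
classifier plugs in through a risk score binarized at a top-fraction cutoff
(default: top 10%).

No clinical data ship with the package. A synthetic-cohort generator
produces rare-outcome tables (~1.5% prevalence) with planted rules of known
confidence and commonality, which is how the pipeline is validated.

## Worked example

```python
from rulerank import AssociationRule, FeatureValueItem, RankingConfig, rank_rules

def item(feature, value, actionable=True):
    return FeatureValueItem(feature, "equals", value, actionable=actionable)

r1 = AssociationRule(
    lhs=(item("ed_visits_past_year", ">=13"), item("steroid_rx_past_year", ">=4")),
    outcome_label="hospital_encounter",
    n_matched=5, n_matched_positive=4, n_positive_total=100)   # C=80%, S=4%
r2 = AssociationRule(
    lhs=(item("ed_visits_past_year", ">=13"), item("controller_adherence", "low")),
    outcome_label="hospital_encounter",
    n_matched=5, n_matched_positive=3, n_positive_total=150)   # C=60%, S=2%
r3 = AssociationRule(
    lhs=(item("prior_admission", "yes"),),
    outcome_label="hospital_encounter",
    n_matched=2, n_matched_positive=1, n_positive_total=100)   # C=50%, S=1%

for sr in rank_rules([r1, r2, r3], RankingConfig(seed=0)):
    lhs = " AND ".join(si.item.item_key for si in sr.sorted_items)
    print(f"rank {sr.rank}  score {sr.score:8.3f}  "
          f"C={100*sr.rule.confidence:5.2f}%  S={100*sr.rule.commonality:4.2f}%  {lhs}")
```

prints

```
rank 1  score  151.000  C=80.00%  S=4.00%  ed_visits_past_year=>=13 AND steroid_rx_past_year=>=4
rank 2  score  150.000  C=50.00%  S=1.00%  prior_admission=yes
rank 3  score  125.002  C=60.00%  S=2.00%  controller_adherence=low AND ed_visits_past_year=>=13
```

Although `r2` beats `r3` on both confidence and commonality, after `r1` is
ranked first both of `r2`'s items are stale (`ed_visits` shared with `r1`),
its diversity term collapses from 1 to `(e⁻⁵+1)/2 ≈ 0.503`, and the
single-item rule `r3` — bringing entirely new information — overtakes it.
Within rank 3, the fresh item `controller_adherence=low` is displayed before
the already-seen `ed_visits_past_year=>=13`.

## Command line

Each stage is a subcommand; `run-all` chains them on a YAML config (or, with
no config, on a freshly generated demo cohort):

```bash
rulerank simulate --n 20000 --seed 7 --out cohort.csv --truth truth.json
rulerank discretize --in cohort.csv --outcome outcome --out map.json
rulerank mine --in cohort.csv --outcome outcome --map map.json --out rules.json
rulerank evaluate --scores scored.csv --outcome outcome --fraction 0.10 --out metrics.json
rulerank explain --rules rules.json --patients scored.csv --out explanations.json
rulerank rank --explanations explanations.json --n 3 --seed 17 --out ranked.json
rulerank sweep --patients scored.csv --rules rules.json --param w_d --grid 0,25,50,100 --out sweep.csv
rulerank run-all --out-dir demo_run --seed 5
```

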
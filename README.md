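# jdorsp

Mining **jumping diagnostic-odds-ratio sequential patterns (JDORSP)** from
labeled multivariate clinical time series.

## The problem

In intensive-care settings (the motivating domain is an Intensive Care Burns
Unit, with six daily variables: fluid intake INC, diuresis DIUR, fluid
balance BAL, bicarbonate BIC, arterial pH, base excess BE), frequent
sequential pattern mining over discretized daily measurements produces
hundreds of thousands of patterns — far too many for clinical review.  Most
interestingness measures prune that set only modestly.

JDORSP selection keeps a pattern only when its epidemiological role *flips*
upon a one-item extension: a pattern significantly associated with survival
(a protection factor) whose extension is significantly associated with death
(a risk factor), or vice versa.  Each such pair describes an abrupt jump in
prognosis caused by a single additional observation — e.g. "pH normal three
days running" protects, but "… followed by very high fluid balance" is
strongly risky.  The selection needs no user-chosen threshold beyond the
mining support, and reduces the pattern set by orders of magnitude.

## Method

1. **Discretization** — each continuous attribute is cut into left-closed
   intervals `[a, b)` by a named scheme (`expert` clinical reference ranges
   or `ucpd` automatic cut points, both shipped as constants; custom schemes
   load from YAML).  A patient becomes a day-ordered sequence of itemsets of
   symbols such as `PH_3` (normal pH).
2. **Mining** — all frequent multivariate sequential patterns, written with
   the temporal operators `<` (before) and `=` (same day), e.g.
   `BAL_4 < BAL_4 < DIUR_2 = PH_4`.  Patterns grow by S-extensions (new
   later itemset) and I-extensions (enlarge the last itemset); supports are
   counted per outcome class, with a pattern kept when frequent among
   survivors **or** among non-survivors (`ceil(minsup × class size)`, `≥`).
3. **Scoring** — each pattern's 2×2 table (carrier × outcome) gives the
   diagnostic odds ratio and its test-based 95% confidence interval

       DOR = (TP·TN)/(FP·FN),    CI = DOR^(1 ± Z/Xhm),   Z = 1.96,
       Xhm = sqrt((n−1)(TP·TN − FP·FN)² / ((TP+FP)(FN+TN)(TP+FN)(FP+TN)))

   with a 0.5 added to all cells only when a cell is zero.  Entire CI below
   1 ⇒ significant protection; above 1 ⇒ significant risk.
4. **Selection** — JDORSP families (significant parent, opposite-significant
   extensions; `all` or beam-search `best` mode), plus two threshold-free
   baselines: jumping emerging patterns (JEP: support in exactly one class)
   and CI non-overlap (both CIs exclude 1 and are disjoint).  Families are
   ranked by the surprisingness score `SUR = max |DOR(p) − DOR(x)|` over a
   parent's extensions.

A seeded synthetic-cohort generator with plantable class-conditional motifs
makes the whole pipeline testable end to end without clinical data.

## Worked example

Score a pattern carried by 279 of 465 patients (43 of the cohort's 87
deaths among the carriers):

```python
import jdorsp as j

t = j.build_contingency(carriers_died=43, carriers_total=279,
                        cohort_died=87, cohort_total=465)
r = j.diagnostic_odds_ratio(t)
print(f"DOR = {r.dor:.2f}, 95% CI = ({r.ci_low:.2f}, {r.ci_high:.2f}), "
      f"{r.classification.value}")
```

```
DOR = 0.59, 95% CI = (0.37, 0.94), PROTECTION
```

The carriers die less often than the cohort (DOR < 1, CI entirely below 1):
a statistically significant protection factor.

Run the pipeline on a synthetic cohort with a planted jump (a protective
parent `PH_0 < PH_0` whose S-extension `BAL_4` is planted with a
class-conditional odds ratio of 16):

```python
from jdorsp import CohortConfig, MotifSpec, simulate_database, mine_frequent
from jdorsp import select_jdorsp, attach_stats, parse_pattern, Item
from jdorsp.select import report_frame

motif = MotifSpec(parse_pattern("PH_0 < PH_0"), Item.parse("BAL_4"), "S",
                  p_parent=(0.5, 0.8), p_extension=(0.8, 0.05))
config = CohortConfig(n_patients=2000, motifs=(motif,), seed=7)
db = simulate_database(config)
result = mine_frequent(db, minsup=0.16, max_length=3)
report = select_jdorsp(result, stats=attach_stats(result), mode="best")
print(report_frame(report).head(4).round(2).to_string(index=False))
```

```
id              pattern  sur  dor  ci_low  ci_high  patients  deaths  pct_death    meaning        direction
 1          PH_0 < PH_0 5.72 0.25    0.20     0.31      1513     185       0.12 PROTECTION PROTECTION->RISK
1A  PH_0 < PH_0 < BAL_4 5.72 5.97    4.70     7.58       350     159       0.45       RISK PROTECTION->RISK
 2         PH_0 < INC_1 5.03 0.27    0.22     0.35      1550     202       0.13 PROTECTION PROTECTION->RISK
2A PH_0 < INC_1 < BAL_4 5.03 5.30    4.16     6.74       344     150       0.44       RISK PROTECTION->RISK
```

The planted flip tops the ranking: patients with two severe-acidosis days
(`PH_0 < PH_0`) mostly survive in this cohort (12% death among carriers),
but once very high fluid balance (`BAL_4`) follows, 45% die.  The mined
extension DOR (5.97) sits below the planted odds ratio of 16 because the
default baselines also produce `BAL_4` days by chance, diluting the
planted contrast; the recovery experiment in the test suite zeroes the
motif items' baseline mass so the planted value is recovered exactly.

The same flow is available from a shell via the `jdorsp` console script
(`simulate`, `discretize`, `mine`, `select`, `rank`, `run`).

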
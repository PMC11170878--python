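# Methods

This note documents the models, conventions and numerical choices behind
the package, the assumptions of the synthetic-data generator, and known
limitations.

## Sequence and pattern model

A patient record is an ordered list of itemsets indexed by integer day
(0-based).  Only the *order* of days carries meaning: patterns use the
operators `<` (strictly earlier day) and `=` (same day); the "after"
operator is redundant because every relation is stated from the earlier
point.  Pattern length counts item instances, so `BAL_4 < BAL_4 < DIUR_2 =
PH_4` is a 4-pattern over three days.

Containment follows the standard subsequence semantics: strictly increasing
element positions, each pattern itemset a subset of a single sequence
itemset (itemsets never split across days), gaps allowed.  Two pattern
itemsets may not map to the same day — implied by the strictly increasing
positions.  Greedy earliest matching is exact for this relation and is the
basis of both the reference containment routine and the miner's vectorized
counting; both are checked against an exhaustive all-embeddings enumerator.

Canonical order inside an itemset is attribute name alphabetically, ties by
interval index.  Rendering and parsing of pattern strings are exact
inverses on canonical patterns.

## Discretization

k strictly increasing cut points define k+1 intervals indexed 0..k, all
left-closed/right-open `[a, b)` with open outer ends; a value exactly on a
cut belongs to the higher interval.  One consistent rule is applied even
around negative thresholds and at interval ends whose printed open/closed
marks in the source tables are typographically inconsistent (one pH
interval is printed closed on the right; adopting `[a, b)` everywhere is
the single reading compatible with the neighbouring intervals).

Two constant schemes ship for the six ICBU attributes (units: INC cc, DIUR
and BAL in dc, BIC mmol/L, PH unitless, BE mEq/L): `expert` (clinical
reference ranges; PH has 7 intervals from severe acidosis `PH_0` to severe
alkalosis `PH_6`) and `ucpd` (automatic correlation-preserving cut points,
5 intervals per attribute).  The UCPD *algorithm* is out of scope; only its
published cut points are shipped.  Custom schemes round-trip through YAML
(`{name, cut_points: {ATTR: [...]}}`).

Missing daily measurements simply produce no item (smaller itemsets; days
with no measurements are dropped), which is the documented behaviour in the
absence of any stated convention for the original data.

## Mining

`mine_frequent` is a prefix-growth enumeration.  Every pattern is generated
exactly once from its canonical parent (delete the last-added item):
S-extensions append a new singleton itemset; I-extensions add an item
strictly greater (canonical order) than the last item of the last itemset.
Frequency is anti-monotone per class, so pruning at infrequent patterns
loses nothing.

Thresholding: a pattern is frequent when its support is at least
`ceil(minsup × class size)` (`≥` comparison — a pattern hitting the bound
exactly is kept; the tie rule is not specified by the method's description,
so the inclusive reading was fixed once).  In `per-class` mode (the
default, matching the survivors/non-survivors split of the original
analysis) the result is the union of patterns frequent in either class,
with both class supports recounted over the full cohort; `global` mode is
provided for generality.

Support counting stores, per sequence, one 64-bit day-position mask per
item (sequences are limited to 63 elements, far beyond the 5-day study
window).  The greedy embedding advances by taking the lowest set bit of the
current itemset's mask above the previous match position, vectorized across
all supporting sequences of the parent; the incremental step is exact
because greedy earliest positions dominate every other embedding.
Correctness is defined operationally: on randomized micro-databases the
miner must produce the identical pattern set, supports, class splits and
lineage as `brute_force_mine`, an independent generate-and-test oracle that
enumerates all subsequences of the database and counts support by trying
every embedding.  The efficient data structures of specialised
sequential-pattern miners are deliberately not reproduced; any complete
miner is acceptable and the oracle is the contract.

## Odds-ratio statistics

The 2×2 table orients the pattern as a diagnostic test for death: TP =
carriers that died, FP = carriers that survived, FN/TN the non-carriers.
The DOR is the cross-product ratio; the 95% CI is the test-based interval
`DOR^(1 ± Z/Xhm)` with Z = 1.96 and Xhm the square root of the
Mantel–Haenszel chi-square (with the n−1 factor).

The 0.5 continuity correction is applied to **all four cells**, but **only
when at least one cell is zero**.  The conditional rule is fixed by the
reference per-pattern values: the printed DOR of a 50-carrier/4-death
pattern (0.35) matches the uncorrected cross-product (0.348), not the
always-corrected value (0.385), while the printed zero-cell DOR (0.09)
matches the corrected one.  When corrected, Xhm and n use the corrected
cells.  One published zero-cell value (46.04 for a 5-carrier/5-death
pattern) matches neither the all-cell (50.47) nor a single-cell (46.10)
correction exactly, and the upper zero-cell CI bounds deviate similarly
(computed 0.86 vs printed 0.90 for the 22-carrier zero-death pattern);
these appear to reflect a different internal convention in the original
implementation, are confined to zero-cell intervals, and are documented
rather than chased — no non-degenerate printed value deviates.

Classification: PROTECTION iff the entire CI is below 1, RISK iff entirely
above 1, otherwise NOT_SIGNIFICANT.  A table with zero cross-product
difference (DOR = 1, Xhm = 0) carries no information; its CI is reported as
(0, ∞) and it is never significant.  Z is configurable but defaults to
1.96 everywhere.

SUR (surprisingness) is the maximum absolute DOR difference between a
parent and its extensions.  Report tables use the 2-decimal-rounded DORs in
the difference (so a printed pair 0.59/4.06 yields SUR 3.47 exactly);
internally full precision is kept, and `surprisingness(..., rounded=...)`
exposes both conventions.

## Selection

"Extension" always means the miner's one-step lineage (length l+1, single
S- or I-extension), never an arbitrary superpattern, and only frequent
extensions exist.  JDORSP emits a family per significant parent with at
least one opposite-significant extension; same-direction or non-significant
extensions are excluded from the family.  `best` mode keeps one extension:
lowest DOR under a RISK parent, highest under a PROTECTION parent (the
beam-search convention fixed by the worked example in the source analysis,
which picks the smallest-DOR protective extension); ties break on the
canonical pattern string.  Maximising |ΔDOR| instead was considered and
rejected because the worked example pins the extremal-DOR reading.

The CI non-overlap baseline keeps parent/extension pairs whose CIs both
exclude 1 and do not overlap; overlap uses closed intervals, so
boundary-touching intervals count as overlapping (conservative choice; the
source is silent).  Under this baseline a family's extensions can be
same-direction, and `best` mode picks the extension farthest from the
parent's DOR.  Every JDORSP pair is also a non-overlap pair (opposite-side
significant intervals cannot meet across 1); this containment is asserted
on synthetic cohorts in the tests.  JEP returns patterns supported in
exactly one outcome class.

Families are ranked by descending SUR; the report CSV lists one row per
parent (numbered 1..) and per extension (1A, 1B, ...) with DOR, CI,
carriers, deaths, % death and classification.

## Synthetic cohorts

Defaults emulate the study conditions: 465 patients, death rate 87/465 ≈
18.7%, 5 days, six attributes with expert-scheme interval counts.  Baseline
items are drawn independently per (patient, day, attribute) with 0.8 mass
on the clinically normal interval and the rest uniform — most measurements
of most ICU patients sit in or near the reference range, and independence
is the simplest null consistent with the method's assumptions.  What the
generator does *not* emulate: day-to-day autocorrelation, cross-attribute
physiology, missing measurements, and static covariates; passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the assumed null, not clinical validity on real trajectories.

Motifs overwrite baseline items on randomly chosen increasing days (keeping
the day count fixed), with class-conditional plant probabilities for the
parent and, conditionally, one S- or I-extension item.  The closed-form
expected contingency table ignores accidental baseline occurrences of the
motif items, so it is exact only when those items carry no baseline mass;
the recovery experiment uses such a configuration (parent `PH_0 < PH_0`
planted at 0.5 died / 0.8 survived — expected parent DOR 0.25 — with
S-extension `BAL_4` at 0.8 / 0.05, giving a cohort-level extension DOR of
exactly 16).  Everything is drawn from a single seeded NumPy generator;
identical configs produce byte-identical output.

### Recovery experiment and CI calibration

The acceptance suite runs 50 seeded replicates at n = 2000, mining at 16%
support (the upper end of the thresholds used in the original analysis)
with pattern length capped at 3 (one more than the planted parent — the
scale at which the planted family lives; the cap keeps each replicate to
well under a second of mining).  The planted family must be returned by
`select_jdorsp` in at least 90% of replicates; in practice detection is
50/50.

The mined extension's CI covers the planted DOR in roughly 86–90% of
replicates, not 95%: a direct Monte-Carlo oracle (binomial draws of the
exact planted table, no mining) puts the true coverage of the test-based
interval at ≈ 0.895 for this table, a known property of test-based
(Miettinen) intervals far from OR = 1.  The coverage test therefore asserts
agreement with the oracle-computed 0.895 (within 3σ of 50 draws) rather
than a nominal level the interval does not attain.  This undercoverage is a
limitation of the CI construction itself, inherited from the method being
implemented; it slightly inflates significance calls for extreme DORs.

A null cohort (no motif) yields JDORSP families only through joint chance
significance of a parent and an oppositely-significant extension; the test
bounds the family count loosely at 5% of lineage edges.  No
multiple-testing correction is applied anywhere — the method under study
defines significance per pattern, and the selection's stringency (two
opposite significant calls) is its only guard; across thousands of mined
patterns some false families are expected and observed.

## Degenerate inputs and edge conventions

* Empty pattern: length 0, contained in every sequence; the parser rejects
  the empty string (an empty pattern is only constructible
  programmatically).
* Empty record set: discretization yields an empty database; mining an
  empty database is an error, as is per-class mining with an empty class.
* Duplicate (patient, day, attribute) measurements and unknown attributes
  are errors naming the offending key; inconsistent per-patient labels are
  errors.
* Tables with a zero margin always contain a zero cell, so the continuity
  correction guarantees finite statistics; table totals below 2 are
  rejected.

## Problem sizes

Defaults throughout the tests are sized to the method's own study
conditions (cohorts of 300–2000 patients, 5 days, 6 attributes, supports
16–20%, pattern length ≤ 3 where the planted structure lives); the
brute-force oracle is guarded to ≤ 8 sequences, ≤ 8 items, length ≤ 12,
which is ample for exhaustive verification.
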
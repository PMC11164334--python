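# Methods

## Data model and counting semantics

The atomic observation is a use report (informant *i*, species *s*, ailment
category *u*). Repeated identical triples are collapsed before any index is
computed: a use report counts informants reporting a use, not repetitions
within an interview. The informant denominator N is always the roster size,
never the number of distinct informants appearing in the report table, so
informants who cite nothing still dilute RFC and CI.

FC counts distinct informants per species; UR counts distinct (informant,
category) pairs, so UR ≥ FC and hence CI ≥ RFC for every species — both are
asserted as invariants on all simulated data. ICF = (Nur − Nt)/(Nur − 1) is
undefined for Nur ≤ 1 (zero denominator) and *suppressed* — reported with a
status rather than a number — for Nur = 2 or Nt > Nur, mirroring the dash
cells that survey reports print for near-empty categories.

## Printing conventions

Computation is full precision; formatting is a presentation layer:

- category tables (ICF) and percentage tables: truncation toward zero at two
  decimals (20/31 → 0.64, 5/8 → 0.62, 3/8 → 0.37, 69/141 → 48.93%);
- the species index table (RFC, CI): truncation at four decimals
  (20/21 → 0.9523, 26/21 → 1.2380);
- classifier evaluation percentages: round-half-up at two decimals
  (40/42 → 95.24).

Truncation was adopted because it is the unique rule consistent with the
reference tables this package reproduces; rounding half-up reproduces the
evaluation headlines but not the index tables. A small number of printed ICF
cells in the source tables match no arithmetic rule (digestive and cold/flu
print 0.40 where the formula gives 0.393/0.391; skin & hair prints 0.43 where
truncation gives 0.42; a respiratory row with Nt > Nur prints 0.50). The
package always reports the computed value and flags such rows; it never
forces a printed number.

## Preprocessing and features

Text cells are lowercased, whitespace-collapsed and stripped of trailing
punctuation; empty cells map to a `missing` sentinel. Mode of application
collapses its spelling variants to {oral, topical, both, missing}; the single
record with a missing class is removed (and logged) before classification,
and identifier columns (scientific name, vernacular name, voucher) are never
features. Multi-valued cells (parts, preparations) default to one nominal
value — the sorted, normalized set joined with `;` — because the reference
analysis treats each table cell as one nominal attribute; an optional
multi-hot encoding expands them into per-vocabulary binary indicators for
sensitivity analysis. The `use_category` feature is the species'
first-listed medicinal use mapped through an editable phrase→category CSV
shipped with the fixture; the mapping is data, not code, because no published
assignment of free-text phrases to the 14 categories exists.

Derived products ("oil of fruit", "juice of root") canonicalize to the
product labels `oil`/`juice` rather than the underlying part. Part and
preparation percentages use total label *mentions* as the denominator (a
species contributes one mention per distinct label); per-species
denominators cannot sum to 100% when rows are multi-valued.

## The decision tree

A reference C4.5-style inducer over nominal attributes: multiway splits (one
branch per observed value), gain ratio as the criterion (features with zero
split information or zero gain are excluded), stopping at pure nodes, nodes
smaller than 2·min_leaf, or when no informative feature remains, and
requiring at least two branches with min_leaf records for a split to stand.
Defaults are min_leaf = 2 with pessimistic pruning at confidence 0.25 — the
conventional J48 settings. Pruning estimates a node's errors as n times the
upper binomial confidence bound at the given confidence and collapses any
split that does not beat the node's own leaf estimate by more than 0.1
errors, bottom-up.

Determinism is part of the contract: among tied gain ratios the feature
earliest in the declared feature order wins; among tied leaf classes the
class most frequent in the parent, then lexicographically smallest; unseen
feature values at prediction time route to the child trained on the largest
record mass. Leaf scores are Laplace-smoothed (+1) class frequencies, so ROC
curves have no degenerate 0/1 ties. One consequence of honest C4.5 stopping
semantics: parity-structured tables (every single feature has zero gain) are
not memorized, because no split is ever justified — the memorization
invariant is therefore only guaranteed when some single feature carries
signal.

Alternative learners (SVM, neural network, logistic regression) are not
reimplemented; a small classifier contract (`fit`/`predict`/`predict_scores`)
plus a one-hot scikit-learn adapter lets them be plugged into the same
resampling protocols when a comparison is wanted.

## Evaluation protocols

The stratified 70–30 holdout sizes its test set as round(0.3·n) with
per-class quotas apportioned by largest remainder; classes with fewer than
two records stay in training with a warning. Stratified 10-fold
cross-validation (scikit-learn's StratifiedKFold, shuffled, seeded) tests
every record exactly once; the headline accuracy is the mean of per-fold
accuracies, with the pooled confusion matrix reported alongside for the
agreement metrics. Precision/recall/F default to support weighting — the
convention under which weighted recall equals accuracy, matching how the
reference comparison table reports identical precision/recall next to the
accuracy. Kappa and AUC are reported as undefined (null) when their
denominators degenerate (single-class truth or marginals).

## The synthetic generator

`simulate_survey` emulates the structure of a small field survey: each
informant cites each species independently (probability `citation_rate`,
optionally per species), each citation lands in the species' primary category
plus a 1+Poisson number of extra categories, and a coupling ρ ties a species'
preparation to its application-mode class (liniment → topical with
probability ρ, non-liniment → oral with probability ρ), giving the
mode-prediction task a known Bayes accuracy max(ρ, 1−ρ). The age–knowledge
slope is specified in use-report units; the citation-probability shift is
divided by the mean reports-per-citation so the OLS regression recovers the
configured slope without bias (verified unbiased empirically across seeds).
Ground-truth counters are recorded from the realized draws during generation,
independently of the event-level pipeline, and the two aggregation paths are
required to agree exactly for any seed.

Defaults mirror the study conditions the package models: 21 informants aged
28–81, 141 species, 14 categories, citation rate 0.055 (a few hundred
expected reports), liniment share 0.14, ρ = 0.9. What the generator does
*not* emulate: informant-to-informant correlation (shared cultural knowledge
makes real citations non-independent), multi-part/multi-preparation species,
free-text noise in category assignment, and family/life-form structure that
correlates with usage. Passing tests therefore demonstrate correctness of the
counting, index arithmetic and learning machinery under the stated sampling
model — not that the tree would achieve any particular accuracy on a new
field survey.

## The packaged fixture

The species table (141 records, 43 families), category list, presence/absence
matrix (141 species × 14 prior studies) and phrase→category map ship as CSVs
transcribed from the published tables. The informant-level citation pattern
was never published, so the use-report table is a deterministic
reconstruction that satisfies every published marginal simultaneously:
per-category citation/species counts (Σ = 222), the five per-species
use-report totals given in the running text (26, 22, 21, 20, 20), and the
frequency of citation implied by each of the 22 published RFC values
(FC = RFC × 21). Pool membership is weighted toward older informants so the
fixture also exhibits the published positive age–knowledge trend. All
constraints are asserted at build time; only marginal fidelity is claimed.

Known irreducible discrepancies, recorded in `FIXTURE_NOTES`: two published
category rows are infeasible as citation events (respiratory: 3 citations
over 4 species; cardiac: 2 over 3) and are realized with 3 and 2 species; the
published CI values of the 22 ranked species imply ~340 use reports, which
contradicts the published total of 222, so only the five explicitly printed
UR totals are enforced; the presence matrix as printed has one all-zero row
(code 19) that is nevertheless not flagged as a first report — a single
prior-study cell is repaired (synthetically, column B) so the matrix agrees
with its own footnote and the published count of 57 novel species; and the
text's "18 Lamiaceae" is transcribed as the 17 rows the table actually
enumerates.

## Problem sizes and numerical choices

Tests and the acceptance script run on the 140-record fixture table and on
simulated surveys of 15–600 species; these sizes give sub-second index
computations and a full suite in a few seconds while keeping every stochastic
check at ≥ 3σ separation from its threshold. Stochastic tests are fixed-seed;
the slope-recovery check averages five seeded surveys and uses a 3σ band on
the mean, the same convention as the FC-convergence check. Ties in gain
ratio, leaf majorities and dense ranks are broken deterministically as
described above; ICF/kappa/AUC degenerate cases return explicit
undefined/suppressed statuses rather than NaN.
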
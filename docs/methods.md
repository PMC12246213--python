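# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `chdnet`, in the order the pipeline runs them. Every number
quoted here is computed by the test suite, the analysis drivers or
`scripts/acceptance.py`; nothing is asserted that the code does not
reproduce.

## Data model

All variables are binary presence/absence flags over patients: damaging-
genotype flags per gene pathway (a damaging genotype means a prioritized,
likely-pathogenic variant or biallelic genotype in that pathway), CHD
phenotype-category flags, an extracardiac-anomaly flag, surgical
risk-category flags, and post-operative outcome flags. A cohort matrix
stores cells in {0, 1, missing}; a per-variable missingness cap of 10% is
enforced at load (override available) as a cohort-construction rule.
Continuous or multi-level variables are out of scope by design.

## Synthetic cohort generator

The generator owns a ground-truth Bayesian network (DAG + CPTs) over ten
variables:

| variable | role | source of its CPT |
|---|---|---|
| CHRMdGV, CILIAdGV | genotype | independent roots, prevalences 5.8% / 5.1% |
| LVO, HTX, ECA | phenotype / extracardiac | closed-form from (marginal, absolute RR, parent prevalence) |
| HLHS | phenotype | deterministic nesting: P(HLHS=1 \| LVO=0) = 0 |
| STAT45 | surgical | fixed table over (HLHS, HTX) |
| MORT, ARREST, VENT7 | outcome | multiplicative-risk CPT over (CHRMdGV, CILIAdGV, STAT45), solved numerically |

Anchored quantities (in `src/chdnet/presets/pcgc_like.yaml`) are the
cohort-level summaries the generator must reproduce **exactly under CPT
enumeration**: damaging-genotype union prevalence 10.6% (the two pathway
flags jointly absorb the full cohort prevalence; the per-pathway split is
not separately anchored), LVO marginal 0.287, HTX 0.097, ECA 0.399,
absolute RRs LVO|chromatin = 1.6, HTX|cilia = 2.6, ECA|chromatin = 2.09,
and network-level relative RRs for mortality / arrest / prolonged
ventilation of 1.8 / 1.7 / 1.6 against the chromatin flag and 1.4 / 1.5 /
1.4 against the cilia flag. Outcome CPTs are parameterized as
`base · a^chrm · b^cilia · c^stat` and `(base, a, b)` are solved with a
root finder against exact enumeration so the anchors hold to 1e-10; the
STAT45 multipliers `c` (4.0 / 3.5 / 3.0) and the outcome base rates
(mortality 4.5%, arrest 5%, ventilation >7 d 15%) have no published values
and were fixed once at clinically plausible levels for a severe-CHD
surgical cohort. The HLHS-within-LVO fractions (30% / 45% with a damaging
chromatin genotype) concentrate the chromatin signal in HLHS, mirroring the
reported 1.9-fold HLHS enrichment qualitatively.

Cohorts are drawn by seeded ancestral sampling in a fixed topological
order; missingness is injected MCAR (each cell independently, rate capped
at 10%). The generator emulates the *statistical* structure of the real
cohort — marginals, pairwise enrichments, mediation through surgical
complexity, deterministic phenotype nesting, MCAR holes — but not: batch or
site effects, informative missingness, correlated genotype flags (gene
lists overlapping), multiple surgeries per patient, or continuous severity.
Passing tests therefore demonstrate correctness of the machinery and
calibration under these idealized conditions, not clinical validity on
registry data.

The same network doubles as an exact oracle: `true_absolute_rr` /
`true_relative_rr` enumerate the full joint (the enumeration asserts total
mass 1) and every recovery, coverage and power test compares against them.

## KNN imputation

Missing cells are filled by majority vote of the k = 10 nearest patients,
with distance = Hamming mismatch rate over mutually observed variables
(normalized by overlap). Determinism: distance ties break by patient order
(stable sort), even votes (5-5) fall back to the variable's marginal mode.
If fewer than k usable donors exist, all donors are used with a warning.
Observed cells are never altered. On scenario data with 5% MCAR, hold-out
masked-cell recovery beats the marginal-mode baseline (asserted in the
suite).

## Collinearity screen

All pairwise phi coefficients (Pearson on 0/1 over pairwise-complete
observations). Zero-variance margins make phi undefined; such pairs are
reported explicitly rather than silently zeroed, and constant variables
are excluded from network stages. On simulated cohorts all pairs are
weakly correlated except LVO-HLHS (phi ≈ 0.5), the expected signature of
deterministic nesting; the screen flags nothing at the default threshold,
matching the intent that final network variables not be collinear.

## Exact structure learning

Scores: natural-log BIC, `LL_hat − (ln N / 2) · q` per family with
`q = 2^|parents|` (r − 1 = 1 outcome parameter per parent configuration;
unseen parent configurations contribute zero likelihood but still count in
q). Counting is done once per dataset by packing rows into integers; one
`bincount` gives the full joint table, subset tables follow by
marginalizing one variable at a time, and family log-likelihoods reduce to
differences of `Σ N ln N` statistics — so the full score table is pure
array arithmetic.

Search is the exact two-phase dynamic program: best parent set within every
candidate subset, then best-sink decomposition over variable subsets, then
order reconstruction. Both DPs are vectorized over popcount layers. Ties
break deterministically: smallest parent-set cardinality, then
lexicographic by node name; sinks lexicographically. No parent cap by
default (networks here have ≤ 10 nodes); a hard guard refuses > 20
variables. No structural priors.

Verification: on random 3-4-variable datasets the DP's score equals
brute-force enumeration over all DAGs (25 / 543 graphs; 100 datasets in the
acceptance suite, exact agreement). BIC score equivalence across
Markov-equivalent DAGs and score decomposability are asserted directly.
Note that only the Markov equivalence class is identifiable: learned edge
directions within a class (e.g. `HLHS -> CHRMdGV`) carry no causal meaning,
which is why display uses the moralized graph (undirect all edges, marry
co-parents of each child; cross-checked against networkx's moral graph).

## Inference and smoothing

CPTs: `P(v=1|pa) = (n₁ + s) / (n₀ + n₁ + 2s)`, additive pseudocount per
outcome count. Policies: fixed s = 0.01 (default) or s = 1/N; s = 0 gives
the MLE with unseen configurations stored as undefined — queries fail
loudly if such a row ever carries probability mass, and tolerate it when
the row is unreachable (e.g. the structural zero HLHS ∧ ¬LVO). Smoothing is
applied wherever CPTs are fitted; inside the bootstrap it is what prevents
zero-state probabilities in resampled data.

Queries are exact. The reference route enumerates the joint over all 2^n
assignments (vectorized); an independently coded einsum factor-contraction
route must agree to 1e-12 relative, and a plain-Python enumeration oracle
in the tests (100 random 5-node networks) pins both down. Approximate
inference is deliberately absent — the networks are small.

## Risk ratios and the bootstrap

Absolute RR = P(target | condition) / P(target); relative RR =
P(targets | factor=1) / P(targets | factor=0), joint targets allowed.
Self-conditioning degenerates to 1 / P(target). Reciprocal coherence
(`relRR · P(T|F=0) = P(T|F=1)`) holds exactly by construction and is
asserted.

Bootstrap: resample patients with replacement, **re-learn the structure**
and refit smoothed CPTs per replicate (a fixed-structure mode exists for
ablation), evaluate the query. Replicates whose resample makes the
conditioning event zero-probability are recorded as undefined and excluded,
never imputed; their count is part of every report row. Summaries:

* `percentile_median` — replicate median with the empirical (5th, 95th)
  percentiles. These are the printed percentiles of the source convention
  even though they span 90% of the distribution while being labelled a 95%
  interval; we follow the printed percentiles and document the discrepancy
  here. The pair is configurable.
* `t_mean` — mean ± t(0.975, B−1) · SD of replicates (the enrichment-table
  convention, interpreting "fitted to a t-distribution" as a t-quantile on
  the replicate spread).

Bars can be asymmetric around the median: the resampling distribution is
constrained by which structures the replicates learn.

Calibration, measured: over 200 synthetic cohorts (n = 2,253, B = 200
scaled down from 1,000 for runtime), the (5, 95) percentile interval for
the absolute RR of LVO given the chromatin flag covers the enumerated true
ratio at ≈ 86-90%, consistent with its 90% nominal span within Monte-Carlo
tolerance (asserted at ±4 percentage points).

Feature selection follows the lenient published rule: a (candidate, target)
pair is kept when the bootstrap-median absolute RR ≥ 1.0. A consequence
worth knowing: for weak pairs, two-variable replicates often learn the
empty graph, whose conditional equals the marginal, so the replicate median
sits exactly at 1.0 and the pair is retained — the screen is a
*pre-filter*, not a significance test.

## Identifiability boundaries (measured, not hypothetical)

BIC-exact learning only includes an edge when its likelihood gain exceeds
`(ln N / 2) · Δq` nats. Two consequences show up in this pipeline's own
numbers:

* **At n = 100,000**, every planted query is recovered within 3 bootstrap
  SE except the relative mortality RR for the cilia flag (estimate ≈ 1.07
  vs true 1.40). The direct cilia→mortality effect (multiplier ≈ 1.3 on a
  2.6% base rate at 5.1% prevalence) carries ~5-8 nats of expected
  log-likelihood against an 11.5-nat penalty (measured ΔBIC ≈ −16.5), so
  the learner — correctly, by its own criterion — omits the edge and the
  plug-in estimate converges to the mediated-only ratio. Any mediation
  split consistent with the anchors has the same property at that n.
* **At n = 2,253** (study scale) the penalty is ~7.7 nats against ~0.15
  nats of direct-edge signal, so *all* direct genotype→outcome edges are
  dropped and network-propagated relative RRs are attenuated toward the
  mediated path (e.g. mortality | chromatin ≈ 1.2-1.3 vs generative 1.8).
  The percentile intervals remain wide enough to reflect this structural
  uncertainty. This is the price of exact score-based selection at small n
  with rare outcomes and is documented rather than patched.

## Phenotype classification

Binary code-indicator features over a phenotype-code vocabulary; five
categories (LVO, HTX, AVC, CTD, OTH). The learner is a pluggable
gradient-boosted tree ensemble (xgboost reference implementation,
`multi:softprob`, single-threaded, seeded); the protocol owned here is:
stratified 5-fold CV grid search minimizing mean multiclass log loss (ties:
lower classification error, then lower log-loss SD), final refit on all
data, argmax assignment, and confidence margin = best − second-best
probability. Default grid: depth {3, 4, 6} × learning rate {0.1, 0.3} ×
rounds {50, 100, 200}; row subsampling exposed as a hyperparameter
(default 1.0). Codes unseen at prediction time are dropped with a warning;
the vocabulary is frozen at training. Metrics are overall accuracy plus
one-vs-rest sensitivity/specificity per class.

The synthetic code generator emits 4 category-specific codes per category
(p = 0.75 in-category, 5% leakage by default) plus 6 shared low-information
codes (p = 0.3 everywhere) — the analogue of descriptors like pulmonary
stenosis that occur in every category. On the mixed scenario at n = 3,000
the protocol reaches ≈ 98% CV accuracy with per-class accuracies ≥ 99%
except the heterogeneous classes, qualitatively matching the high-90s
regime reported for curated-code classification; on the separable scenario
it is exact (CV accuracy 1.0), and accuracy degrades monotonically with
code leakage. Identical-seed retraining is bit-reproducible.

## Problem sizes and numerics

* Exact-learner oracle: 100 random datasets, 3-4 variables, 20-80 rows.
* Inference oracle: 100 random 5-node networks, tolerance 1e-12 relative.
* Parameter recovery: one cohort of n = 100,000, SE from 40 shared
  resampled refits.
* Interval calibration: 200 cohorts × B = 200 replicates (tests);
  100 × 200 in the acceptance script. B = 200 is a runtime-motivated
  scale-down of the 1,000-replicate convention; replicate-SE scaling was
  checked to be unaffected in expectation.
* Score equality comparisons use exact float equality inside the DP (the
  compared values are produced by the same arithmetic) and 1e-9 absolute
  tolerance between independent scoring routes.
* All RNG flows through `numpy.random.default_rng` with explicit seeds;
  bootstrap, sampling, CV splits and xgboost are all seeded, making every
  pipeline run byte-reproducible from its config (asserted on TSV/JSON
  outputs).

## Known limitations

* Learned edge *directions* are reported as found but only the equivalence
  class is meaningful; use the moralized export for display.
* The generator's two genotype flags are independent; real gene lists
  overlap (shared genes between chromatin and curated-CHD lists), which
  would induce correlation the screen should then flag.
* Bootstrap coverage is validated for a well-estimated query; for very
  rare joint events (counts of 1-5) intervals are rough, wide, and can be
  structurally truncated — the same caveat the source analyses attach to
  their rare-context estimates.
* The feature screen's RR ≥ 1 rule is intentionally lenient (see above).
* No survival/time-to-event modelling; outcomes are presence/absence.
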
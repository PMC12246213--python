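# chdnet

Genotype-aware forecasting of outcomes after congenital cardiac surgery,
built on exact discrete Bayesian networks.

Children undergoing surgery for congenital heart defects (CHD) differ
enormously in lesion severity, surgical complexity and genetic background.
This package implements, as a tested and reusable pipeline, an analysis in
which per-patient *damaging-genotype* flags (presence of a damaging variant
in a gene pathway such as chromatin-modifying or cilia-related genes), CHD
phenotype-category flags, extracardiac-anomaly status, surgical risk
category (STAT 4-5) and post-operative outcome flags (mortality, cardiac
arrest, ventilation >7 days) are modelled jointly as binary nodes of a
Bayesian network, and personalized risks are read off the fitted network by
exact probabilistic inference. It is aimed at quantitative researchers in
clinical genomics / systems biology who want the full chain — cohort
handling, structure learning, inference, resampling uncertainty — in one
place, with exact algorithms and oracle-tested components.

## What it computes

* **Exact structure learning.** The network structure is the globally
  BIC-optimal DAG, found with the Silander-Myllymäki dynamic program (best
  parent sets over the subset lattice, then best-sink decomposition) —
  no hill climbing. Family scores use the natural-log BIC,
  `LL_hat − (ln N / 2) · 2^|Pa| · (r−1)` with `r = 2`.
* **Exact inference ("network propagation").** CPTs are fitted with
  additive smoothing `P(v=1|pa) = (n₁+s)/(n₀+n₁+2s)` (s = 0.01 by default,
  `1/N` selectable) and conditional probabilities are computed by exact
  summation over hidden variables.
* **Two risk ratios.** For a target T and conditioning variable C:
  absolute RR = `P(T=1 | C=1) / P(T=1)` (enrichment over the cohort
  baseline) and relative RR = `P(T | F=1) / P(T | F=0)` for a factor F,
  where T may be a joint assignment (e.g. mortality ∧ LVO).
* **Bootstrap uncertainty with structure re-learning.** Patients are
  resampled with replacement and the *whole* network — structure and CPTs —
  is re-learned per replicate; intervals are either the empirical 5th-95th
  replicate percentiles around the median, or mean ± t(0.975, B−1)·SD.
* **Feature selection** (pairs kept when the bootstrap-median absolute RR
  ≥ 1), **collinearity screening** (phi coefficients), **KNN imputation**
  (k = 10, Hamming distance, majority vote) and a **gradient-boosted
  phenotype classifier** that assigns each patient to one of five CHD
  categories (LVO, HTX, AVC, CTD, OTH) from binary phenotype-code
  indicators, with 5-fold cross-validated grid search and a
  best-minus-second-best confidence margin.
* **A calibrated synthetic-cohort generator.** A ground-truth DAG+CPT model
  whose enumerated marginals and risk ratios reproduce published
  cohort-level anchors (10.6% damaging-genotype prevalence, HLHS nested
  inside LVO, relative RRs 1.4-1.8 for adverse outcomes, absolute RRs 1.6
  and 2.6 for phenotype enrichment), used both to generate data and as an
  exact oracle in tests.

## Worked example

```python
from chdnet import (pcgc_like_scenario, sample_cohort, inject_missingness,
                    knn_impute, learn_exact, fit_cpts, relative_rr,
                    RiskQuery, bootstrap_risk)

gtn = pcgc_like_scenario()                      # calibrated ground truth
cohort = knn_impute(inject_missingness(
    sample_cohort(gtn, 2253, seed=1), 0.05, seed=2), k=10)

dag = learn_exact(cohort)                       # exact BIC-optimal DAG
fn = fit_cpts(dag, cohort, smoothing=0.01)
print("edges:", dag.edges)
print("relative RR of mortality given a damaging chromatin genotype:",
      round(relative_rr(fn, {"MORT": 1}, "CHRMdGV"), 2))

rq = RiskQuery("absolute", {"LVO": 1}, "CHRMdGV")
est = bootstrap_risk(cohort, ["CHRMdGV", "LVO"], rq, B=200, seed=3,
                     summary="t_mean")
print(f"absolute RR of LVO given chromatin dGV: {est.point:.2f} "
      f"(95% CI {est.ci_low:.2f}, {est.ci_high:.2f}), "
      f"B={est.B}, undefined replicates={est.n_undefined}")
```

Output:

```
edges: [('CHRMdGV', 'ECA'), ('HLHS', 'CHRMdGV'), ('HLHS', 'LVO'), ('HLHS', 'STAT45'), ('HTX', 'CILIAdGV'), ('HTX', 'STAT45'), ('STAT45', 'ARREST'), ('STAT45', 'MORT'), ('STAT45', 'VENT7')]
relative RR of mortality given a damaging chromatin genotype: 1.27
absolute RR of LVO given chromatin dGV: 1.84 (95% CI 1.53, 2.15), B=200, undefined replicates=0
```

The learned edges recover the generative skeleton up to Markov equivalence
(edge directions within an equivalence class are not identifiable from
observational data). The pairwise absolute RR brackets the planted 1.6-fold
LVO enrichment; the network-propagated relative mortality RR at n = 2,253
is attenuated relative to the generative 1.8 because the weak direct
genotype→outcome dependence falls below the BIC penalty at that sample size
— see `docs/methods.md` for the quantitative analysis.

## The analysis, step by step

Numbered drivers under `analysis/` run the stages in order and write their
tables to `results/`:

```bash
python analysis/01_simulate_cohort.py      # cohort TSV + baseline frequencies
python analysis/02_impute_and_screen.py    # KNN imputation, phi screen, feature selection
python analysis/03_learn_networks.py       # exact networks, JSON + moralized DOT
python analysis/04_risk_estimates.py       # bootstrapped absolute/relative RRs
python analysis/05_classify_phenotypes.py  # phenotype classifier, CV metrics
```

Each script accepts `--seed` (default 1) and `--outdir`. The same stages
are scriptable through the `chdnet` CLI (`simulate`, `impute`, `screen`,
`learn`, `estimate`, `classify`, `export`, `run`) or a single YAML config
via `chdnet run --config pipeline.yaml`.

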
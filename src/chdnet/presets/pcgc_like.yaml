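# Calibration anchors for the PCGC-like synthetic surgical cohort.
#
# Anchored quantities (prevalences, absolute/relative risk ratios) are the
# published cohort-level summaries the generator must reproduce exactly under
# CPT enumeration; conditional-probability tables are SOLVED from these
# anchors at load time, so the file records the study conditions rather than
# a hand-tuned parameterization. Quantities without a published value
# (outcome base rates, surgical-category prevalence, HLHS fractions) are
# field-plausible choices fixed once; see docs/methods.md.
version: 1
name: pcgc_like
n_patients: 2253
missing_rate: 0.05

# Damaging-genotype pathway flags (independent roots). The two flags jointly
# carry the cohort's 10.6% damaging-genotype prevalence:
# P(CHRM or CILIA) = 1 - (1-0.058)(1-0.051) = 0.1060.
roots:
  CHRMdGV: {role: genotype, prevalence: 0.058}
  CILIAdGV: {role: genotype, prevalence: 0.051}

# Phenotype / surgical layer. "absolute_rr" anchors P(v|parent=1)/P(v);
# CPT rows follow in closed form from (marginal, absolute_rr, parent
# prevalence).
anchored_children:
  LVO:
    role: cardiac_phenotype
    parent: CHRMdGV
    marginal: 0.287          # 647 / 2253
    absolute_rr: 1.6
  HTX:
    role: cardiac_phenotype
    parent: CILIAdGV
    marginal: 0.097          # 219 / 2253
    absolute_rr: 2.6
  ECA:
    role: extracardiac
    parent: CHRMdGV
    marginal: 0.399          # 898 / 2253
    absolute_rr: 2.09

# Deterministic nesting: HLHS only occurs within LVO; damaging chromatin
# genotypes are concentrated in the HLHS subset.
hlhs:
  role: cardiac_phenotype
  parents: [LVO, CHRMdGV]
  p_given:                   # P(HLHS=1 | LVO, CHRMdGV)
    lvo0: 0.0
    lvo1_chrm0: 0.30
    lvo1_chrm1: 0.45

# Highest surgical mortality-risk category (STAT 4 or 5), driven by the most
# severe lesions.
stat45:
  role: surgical
  parents: [HLHS, HTX]
  p_given:                   # P(STAT45=1 | HLHS, HTX)
    base: 0.14
    hlhs: 0.80
    htx: 0.35
    both: 0.90

# Post-operative outcomes. Each outcome has parents
# (CHRMdGV, CILIAdGV, STAT45) with a multiplicative-risk CPT
# base * a^chrm * b^cilia * c^stat; (base, a, b) are solved so the
# enumerated marginal and the two network-level relative risk ratios
# (with/without each damaging genotype) match the anchors.
outcomes:
  MORT:
    role: outcome
    marginal: 0.045
    relative_rr_chrm: 1.8
    relative_rr_cilia: 1.4
    stat_multiplier: 4.0
  ARREST:
    role: outcome
    marginal: 0.050
    relative_rr_chrm: 1.7
    relative_rr_cilia: 1.5
    stat_multiplier: 3.5
  VENT7:
    role: outcome
    marginal: 0.150
    relative_rr_chrm: 1.6
    relative_rr_cilia: 1.4
    stat_multiplier: 3.0
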
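# Default pipeline configuration.
#
# Analysis settings mirror the study design: acute phase = days 1-4,
# significance threshold 0.05, network inclusion at log2 fold change > 1.5,
# critical illness at SOFA >= 12, combined scores A-D.

seed: 0

# Days analysed per-day (tests, networks, scores, associations).
analysis_days: [1, 2, 4]

# Acute-phase sampling days; also the running-max update days for the
# time-dependent Cox covariates.
acute_days: [1, 2, 4]

# Later-phase days (informational; per-day analyses can be extended to them).
later_days: [6, 8, 11]

# Two-sided significance level used for Dunnett comparisons and network edges.
alpha: 0.05

# Network node filter: log2(mean sepsis level / mean control level) must
# exceed this (strict) threshold.
fold_change_threshold: 1.5

# Critical illness cut-off: SOFA score on each day >= this value.
sofa_cutoff: 12

# Ward dendrogram cut height on the 1 - r dissimilarity tree.
cluster_cut_height: 0.9

# Combined quantile scores: per-mediator 75th-percentile indicators, summed.
score_sets:
  A: [IL-1b, IL-6, IL-8, IL-10, MCP-1, PAI-1]
  B: [IL-6, IL-8, IL-10, MCP-1, PAI-1]
  C: [IL-6, IL-8, IL-10, MCP-1]
  D: [IL-6, IL-8, MCP-1]

# Synthetic cohort generator. Omit this block (and pass --input to
# `cytonet analyze`) to analyse an existing cohort directory instead.
simulation:
  n_patients: 31
  n_controls: 13
  sampling_days: [1, 2, 4, 6, 8, 11, 15]
  cluster_correlation: 0.7   # latent pairwise log10-scale correlation
  ar_coefficient: 0.8        # day-to-day persistence of latent severity
  baseline_hazard: 0.01      # deaths per day at average severity
  log_hazard_per_severity_unit: 0.8
  followup_days: 28
  discharge_probability_per_visit: 0.15
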
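# cytonet

Acute-phase cytokine-network analysis for septic cohorts.

In sepsis, inflammatory mediators do not act alone: a handful of cytokines
(IL-6, IL-8, MCP-1, the anti-inflammatory IL-10) and the endothelial-injury
marker PAI-1 rise together during the first days after diagnosis, track organ
failure, and carry prognostic information. `cytonet` implements, as a tested
and reusable pipeline, the statistical workflow used to characterise such a
network from a small longitudinal cohort: serial measurements of 11 serum
cytokines plus plasma PAI-1 on days 1, 2, 4, 6, 8, 11 and 15, per-day severity
scores (SOFA, JAAM DIC, ISTH DIC) and 28-day survival.

It is aimed at biostatisticians and clinical researchers who want to apply —
or stress-test — this class of analysis without access to patient data: a
built-in simulator generates cohorts with the same longitudinal, correlation,
detection-limit, severity and survival structure, with known planted truth.

## The analysis

All concentrations x are log10-transformed before analysis. For each
analysis day:

- **Group tests.** Dunnett's many-to-one procedure compares sepsis (or the
  critical / non-critical strata, split at SOFA ≥ 12) against healthy
  controls, with adjusted p-values from the joint multivariate-t null of
  max|t|.
- **Correlation network.** Pairwise Pearson correlations r on the log10
  scale; Ward hierarchical clustering on d = 1 − r; a graph whose nodes are
  mediators with log2(mean sepsis / mean control) > 1.5 (raw-scale means)
  and whose edges are correlations with p < 0.05. Exported as
  GraphML/SIF (Cytoscape-compatible).
- **Combined quantile scores.** For a mediator set M (A–D below), each
  mediator is dichotomized at its cohort 75th percentile and the indicators
  1{x_m ≥ q75(m)} are summed, giving an integer score in 0..|M|:
  A = (IL-1β, IL-6, IL-8, IL-10, MCP-1, PAI-1), B = (IL-6, IL-8, IL-10,
  MCP-1, PAI-1), C = (IL-6, IL-8, IL-10, MCP-1), D = (IL-6, IL-8, MCP-1).
- **Severity associations.** Spearman ρ of every marker and score against
  SOFA / JAAM / ISTH, banded as strong (>0.8), moderate (0.5–0.8), weak
  (0.3–0.5), very weak (0.1–0.3).
- **Survival.** Cox proportional hazards with time-dependent covariates:
  the running maximum of each covariate over acute-phase days 1, 2, 4
  (day 1 value; max of days 1–2; max of days 1–4, carried forward),
  counting-process intervals (0,2], (2,4], (4, min(T,28)], Efron tie
  handling. Hazard ratios are reported Q1→Q3: exp(β(Q3 − Q1)).
- **Prognostic ROC.** Day-1 ridge-penalized logistic models (Gaussian prior
  on slopes, penalty chosen by corrected AIC); Mann–Whitney AUC; DeLong's
  paired test of AUC(SOFA + marker) versus AUC(SOFA only).

## Worked example

```python
from cytonet import (make_cohort, build_day_matrix, control_matrix,
                     pearson_matrix, build_network, spearman_assoc,
                     fit_td_cox)
from cytonet.network import fold_changes
from cytonet.scoring import make_definition, score_table
from cytonet.simulate import SimulationConfig
from cytonet.survival import expand_intervals, score_running_max
from cytonet.markers import SCORE_SETS

cohort = make_cohort(SimulationConfig(seed=1))   # 31 septic + 13 controls
day1 = build_day_matrix(cohort, 1)
controls = control_matrix(cohort)

net = build_network(pearson_matrix(day1), fold_changes(day1, controls))
print(sorted(net.nodes), len(net.edges))

scores = score_table(day1, [make_definition("C", day1)])["score_C"]
assoc = spearman_assoc(scores, day1.severity["sofa"])
print(round(assoc.rho, 2), assoc.strength)

cov, _ = score_running_max(cohort, SCORE_SETS["C"])
fit = fit_td_cox(expand_intervals(cohort.outcomes, cov), name="score_C")
print(round(fit.hr_q1q3, 2), round(fit.p, 3))
```

prints

```
['IL-10', 'IL-6', 'IL-8', 'MCP-1', 'PAI-1'] 10
0.75 moderate
2.04 0.068
```

The five planted cluster mediators pass the fold-change filter and are fully
interconnected on day 1 (5 nodes, all 10 pairwise edges significant);
combined score C correlates moderately (ρ = 0.75) with same-day SOFA; and
the acute-phase running maximum of score C doubles the death hazard per
interquartile step (HR_Q1→Q3 = 2.04), though at n = 31 the Wald test is only
borderline (p = 0.068) — small-cohort behaviour the simulator makes easy to
see.

The same run from the shell:

```bash
cytonet all --config configs/run.yaml --out report/ --seed 1
```

writes `report/` with `cohort/`, `tests/`, `networks/`, `scores/`,
`associations/`, `survival/`, `roc/`, plus a manifest with content hashes.

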
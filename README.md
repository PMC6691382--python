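# mirisk

Prognostic miRNA-signature analysis for metastatic pheochromocytoma /
paraganglioma (PPGL)-style cohorts.

About 15–20% of PPGL patients develop metastases, and no validated molecular
marker identifies them at diagnosis beyond *SDHB* mutation status. One route
to such a marker is a multi-cohort miRNA analysis: find miRNAs differentially
expressed between metastatic and non-metastatic tumors in several
independently profiled sub-series, confirm them directionally in a validation
series, combine the best ones with *SDHB* genotype into a simple risk
classifier, relate them to time to progression, locate their candidate mRNA
targets by negative expression correlation, and check whether the signature
is measurable in patient serum. `mirisk` implements that entire analysis as a
tested, reusable library + CLI, together with a synthetic-cohort generator so
every step can be exercised and calibrated without access to patient data.

## What it computes

* **Differential expression (per sub-series).** For each miRNA, a two-sided
  Mann–Whitney test of metastatic vs non-metastatic tumors with
  Benjamini–Hochberg FDR within the series; a miRNA passes at
  FDR &lt; 0.05 and |log₂FC| ≥ 0.75, and a cross-series **consensus** keeps
  miRNAs passing in ≥ *k* series with a consistent direction. A one-sided,
  direction-constrained variant confirms pre-specified candidates in a
  validation series.
* **miR-SDHB risk model.** Each miRNA is dichotomized at its *within-series*
  median (batch-aware), and metastatic status is modelled by stepwise
  logistic regression (forward LR entry α=0.05, backward removal α=0.10,
  IRLS fit) with series indicators forced in; a stratum-conditional
  likelihood variant is available. The explicit **miR-SDHB score**
  (0–3 = miR-21-3p high + miR-183-5p high + *SDHB* mutated) is stratified
  with exact Clopper–Pearson intervals and evaluated by ROC/AUC with DeLong
  confidence intervals.
* **Survival.** Time to progression (TTP, days from diagnosis to first
  documented metastasis) with the metachronous cohort rule (events before
  one year excluded), Kaplan–Meier product-limit curves and the log-rank
  test — all implemented from first principles, with an exact small-sample
  log-rank option.
* **Targetome integration.** Candidate targets of a miRNA (union of
  validated-interaction databases) are screened by Spearman correlation
  ρ(mRNA, miRNA) per sub-series; a gene survives only with a strong
  significant negative correlation (P &lt; 0.05, ρ &lt; −0.4) in some series
  *and* either replication in every other series or ≥ 2 concordant probes in
  the triggering series. Pan-cancer-style per-cohort correlation screens and
  drug-sensitivity-signature correlations reuse the same machinery.
* **Seed-site scanning.** Canonical 6mer/7mer-m8/7mer-A1/8mer seed matches in
  3'UTRs, plus single-mismatch 6mers rescued by a short exact match to the
  miRNA 3'-supplementary region (the compensated-site geometry).
* **Circulating miRNAs.** One-sided rank-sum contrasts across serum groups
  (healthy H, non-metastatic B, stable/progressive metastatic Ms/Mp),
  patient-vs-control ROC, and correlation of serum levels with metastatic
  burden.
* **Synthetic cohorts.** `mirisk.simulate` generates all of the above inputs
  with planted effects (Gaussian-copula rank coupling for targets,
  logistic risk components, exponential TTP) and emits the ground truth
  separately, so recovery rates are measurable.

## Worked example

```python
from mirisk.simulate import SimConfig, simulate_cohorts
from mirisk.diffexpr import differential_expression, consensus
from mirisk.risk_model import (dichotomize, build_design, stepwise_logistic,
                               mir_sdhb_score, stratify_by_score,
                               evaluate_classifier)

res = simulate_cohorts(SimConfig(), seed=1)      # 3 series: 150/100/80 tumors
de = [differential_expression(res.mirna[s], res.sheet) for s in res.mirna]
for c in consensus(de, min_series=3):
    print(f"  {c.mirna_id:<20s} {c.direction}")

design = build_design(dichotomize(list(res.mirna.values()),
                                  ["hsa-miR-21-3p", "hsa-miR-183-5p"]),
                      res.sheet)
fit = stepwise_logistic(design,
                        ["hsa-miR-21-3p_high", "hsa-miR-183-5p_high"],
                        forced_terms=design.series_terms + ["sdhb_mutated"])
roc = evaluate_classifier(fit, design.outcome)
print(f"model AUC = {roc.auc:.3f}  (95% CI {roc.ci95[0]:.3f}-{roc.ci95[1]:.3f})")
print(stratify_by_score(mir_sdhb_score(design), res.sheet)
      [["n", "n_metastatic", "fraction"]])
```

prints

```
  hsa-miR-182-5p       up
  hsa-miR-183-5p       up
  hsa-miR-202-5p       down
  hsa-miR-21-3p        up
  hsa-miR-551b-3p      up
  hsa-miR-96-5p        up
model AUC = 0.955  (95% CI 0.934-0.975)
         n  n_metastatic  fraction
score
0       81             0  0.000000
1      116             2  0.017241
2       81            37  0.456790
3       52            45  0.865385
```

The consensus recovers exactly the six planted signature miRNAs with their
planted directions (miR-202-5p is the down-regulated member); the
dichotomized two-miRNA + *SDHB* model separates metastatic from
non-metastatic tumors far better than genotype alone (AUC 0.955 vs 0.697 for
*SDHB* only on the same cohort), and the metastatic fraction climbs from 0%
at score 0 to 86.5% at score 3 — the qualitative behaviour the score is
designed to exhibit.

The same pipeline is scriptable from the shell (`mirisk simulate`, `mirisk
de`, `mirisk consensus`, `mirisk survival`, `mirisk risk`, `mirisk
targetome`, `mirisk seedscan`, `mirisk serum`); all commands write
deterministic TSV/JSON.

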
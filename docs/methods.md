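# Methods

This note records the statistical procedures `mirisk` implements, the
modelling choices that were genuinely open, the defaults of the synthetic
cohort generator and what they do (and do not) emulate, and the numerical
conventions used throughout.

## Statistical primitives

All rank statistics are computed on mid-ranks (ties receive their average
rank). P-values are floored at machine epsilon and never reported as zero.

**Spearman correlation.** ρ is the Pearson correlation of mid-ranks,
computed pairwise-complete (pairs with any missing value dropped; n ≥ 3
required, zero rank variance is an error). The P-value is exact for n &lt; 10
— the complete permutation distribution over all n! orderings of one rank
vector — and the t approximation t = ρ√((n−2)/(1−ρ²)) with n−2 df
otherwise. The threshold is set so that a validation-sized series (n ≈ 50)
uses the conventional t approximation while the exact branch remains
enumerable. The one-sided "negative" mode reports P(ρ\* ≤ ρ_obs), the
direction-constrained test the target cascade uses.

**Mann–Whitney / rank-sum.** U counts pairs favouring the first group (ties
half). P is exact (complete enumeration of the C(n, n₁) labelings) when the
pooled sample is ≤ 12 and tie-free, otherwise a normal approximation with
the standard tie correction and a 0.5 continuity correction. The exact and
continuity-corrected one-sided P agree within 0.01 absolutely at 6 + 6
(verified exhaustively over all U); two-sided P doubles that gap, a direct
consequence of the 2·min convention.

**Benjamini–Hochberg.** Step-up with monotonicity enforced from the largest
p downward; applied within each sub-series for discovery (the analysis is
per-series), optionally across contrasts elsewhere.

**ROC/AUC.** AUC uses the rank-sum identity U/(n₊·n₋), so tied
positive-negative pairs count ½; the curve enumerates descending unique
thresholds, starts at (0,0) and its trapezoidal area equals the AUC exactly.
The 95% CI is DeLong's placement-variance interval — the standard
nonparametric choice when no method is mandated. An AUC ≠ 0.5 test is
provided as the equivalent two-sided rank-sum test and is labelled as such.

**Survival.** The Kaplan–Meier product-limit estimator keeps subjects
censored exactly at an event time in the risk set at that time. The
two-group log-rank statistic uses pooled-risk-set expectations and
hypergeometric variances; its default P-value is the χ²(1) tail, matching
mainstream survival software. Because the χ² tail only approximates the
discrete conditional distribution to O(1/n) (measured gap up to ~0.03 at
8 + 8 subjects), `logrank_test(..., method="exact")` enumerates all label
assignments for cohorts of ≤ 20 subjects; the test suite validates that
exact branch against an independent label-permutation oracle. Note that
adding a subject censored after the last event time *does* change the
product-limit values (the subject enlarges every risk set); the property
tests assert that true behaviour.

## Cohort assembly and dichotomization

TTP cohorts follow the metachronous rule: included are patients with a
documented metastasis at ≥ 365 days, or metastasis-free follow-up &gt; 365
days (censored at last follow-up). "≥ one year" is read inclusively, so an
event at exactly day 365 counts as metachronous. Synchronous metastatic
patients and short-follow-up patients are excluded with reason codes, never
silently.

Median splits route at-median values to "low": *high* is defined as strictly
above the median, and low is its exact complement. Dichotomization for the
risk model happens independently per series before pooling — per-series
medians make the indicator invariant to any strictly increasing per-series
transform, which is what lets arrays and sequencing series be pooled without
normalising them to each other.

## The risk model

The metastasis model is an unconditional maximum-likelihood logistic
regression with the series indicator covariates forced in, fitted by
IRLS/Newton (log-likelihood tolerance 1e-8, ≤ 100 iterations). This is the
covariate-adjustment reading of a multi-series design; an exact
stratum-conditional likelihood variant (series as strata; denominators via
the elementary-symmetric-polynomial recursion, so large strata stay
tractable) is available via `mode="conditional"` for comparison, and drops
the intercept and any stratum-constant covariate by construction. Stepwise
selection uses likelihood-ratio tests with SPSS-default thresholds (entry
0.05, removal 0.10), iterated to stability. Perfect separation is flagged
(`convergence=False`, last stable iterate returned) rather than silently
reported; an L2-penalized (`ridge`) fallback is available. Reported AUCs are
apparent (training-data) AUCs and documented as such; no resampling
correction is applied.

*SDHB* status is tri-state; unknown status excludes a patient from models
and scores that need it — for a prognostic marker this is the conservative
choice over assuming wild-type. Whether *SDHB* is forced into the model or
offered to the stepwise pool is the caller's choice (`forced_terms`); both
modes are supported because the published modelling descriptions admit both
readings.

The miR-SDHB score is the plain integer sum of three indicators (miR-21-3p
high, miR-183-5p high, *SDHB* mutated), hence symmetric in its components;
score-level metastatic fractions carry exact Clopper–Pearson 95% intervals,
and an empty score level reports a missing fraction, not 0.

## The targetome cascade

For each miRNA, candidate targets are the gene-symbol union of
validated-interaction database exports (entries deduplicated on miRNA ×
gene × source). The mRNA matrix of each sub-series is restricted to
candidate probes, every probe is Spearman-correlated (two-sided) with the
miRNA, and a gene survives iff

1. some series shows ρ &lt; −0.4 with P &lt; 0.05 (the trigger — significance
   *and* strength are both required), and
2. either every other series has a significantly negative record of the
   gene, or the triggering series carries ≥ 2 distinct probes of the gene
   each individually significant and negative.

The two-probe arm uses the stricter "both probes pass" reading; a lenient
variant (≥ 2 probes present, ≥ 1 passing) sits behind
`multiprobe_rule="lenient"`. The rule is monotone in both thresholds
(raising α or relaxing the ρ cut never removes a survivor), which the test
suite verifies against an independently coded rule evaluator. The
literature-based biological shortlist applied after the cascade in the
original analysis is modelled as a user-supplied allowlist that *marks*
membership and never filters: the cascade hard-codes no gene biology.
Per-cohort screens (mRNA, RPPA protein, or numeric signature-score targets)
report per-cohort ρ/P plus the fraction of cohorts with a significant
negative correlation; cohorts under 10 complete pairs are skipped.

## Seed scanning

Site classes follow the TargetScan convention on the UTR written 5'→3': a
6mer is a match to the reverse complement of miRNA positions 2–7; 7mer-m8
extends one base 5'-ward (position 8); 7mer-A1 adds an A opposite position
1 at the 3' end of the site; 8mer has both. Each location reports its
maximal class by default (nested classes on request). The compensated-site
scan formalises the rescue geometry proposed for imperfect sites: a 6-nt
window matching the seed complement at exactly 5/6 positions qualifies when
an exact 4-nt match to the reverse complement of miRNA positions 13–16 lies
5' of the window on the UTR — where the miRNA 3' arm reaches in the
antiparallel duplex — within 8 nt. Supplementary-region position, patch
length and gap are all configurable; the conventional 13–16 window and an
8-nt reach are defaults, since no published coordinates fix them. No
thermodynamic or conservation scoring is attempted.

## Synthetic cohorts: what the generator emulates

Defaults are the study conditions the package is calibrated under:

* **Three tumor series of 150/100/80 samples** with per-series baseline
  offsets (0, +0.9, −0.7 log2) so that per-series dichotomization genuinely
  matters, and per-series platforms drawing 1 probe (70%) or 2 probes (30%)
  per gene (probe noise SD 0.3).
* **A six-miRNA planted signature** at ±1.2 log2 shift in metastatic tumors
  (five up, one down, mirroring the real signature's directions) among 200
  miRNAs, residual SD 0.5.
* **Metastasis prevalence 0.25** — cohort collections assembled for
  metastasis studies are enriched relative to the 15–20% population
  incidence, and 0.25 keeps ≥ 2 cases per group in the smallest series.
  *SDHB* mutation prevalence 0.3 with odds ratio 3 for metastasis; the
  intercept is solved numerically so the marginal prevalence matches.
* **Twenty planted targets** (10 per classifier miRNA) at population
  Spearman −0.5 among 300 decoy genes, via a Gaussian copula on the miRNA's
  within-series normal scores with latent correlation r = 2·sin(πρ/6) — the
  bivariate-normal rank identity, which gives analytic control of the
  population Spearman (empirical calibration is property-tested). Candidate
  catalogs contain the planted targets plus 150 random decoy candidates per
  miRNA across three synthetic database sources.
* **TTP**: metastatic patients draw exponential event times (median 1000
  days; ×1.5 hazard if *SDHB*-mutated), non-metastatic patients draw
  administrative censoring uniform on 400–3650 days. Exponential times put
  ~22% of events before one year; those become synchronous cases that the
  cohort rule must exclude — deliberate, so the rule is exercised.
* **Serum panels** H/B/Ms/Mp of 10/12/7/7 samples with log-normal levels
  (log2 shifts 0/1.5/2.8/4.4, SD 0.8). The Mp–Ms gap is calibrated to
  δ/σ = 2.0 so the weakest pre-specified contrast (Mp vs Ms at n = 7/7,
  one-sided α = 0.05) has ≈ 0.95 power; a normal-theory power formula
  underestimates what the rank test needs at n = 7, so the calibration was
  done by simulation. Metastatic burden is rank-coupled (ρ = 0.5) to the
  miR-21-3p serum level.

The generator emits the planted truth in a separate object that no analysis
module imports (enforced by a test). What it does **not** emulate: platform-
specific array noise and probe-affinity artefacts, read-count statistics,
normalisation failures, batch effects beyond additive offsets, informative
censoring, or correlated decoy structure (decoys are independent). Passing
recovery tests on these cohorts therefore demonstrates correctness of the
pipeline's logic and calibration of its tests under idealised noise — not
performance on real arrays.

A fully deterministic 12-patient worked toy (2 series, 4 miRNAs, 10 genes,
24 serum samples) with hand-derived expected outputs for every module backs
the smoke tests and the CLI determinism check.

## Numerical conventions and edge cases

* Missing expression values are explicit NaNs; every correlation/test is
  pairwise-complete. Blank cells never become zeros.
* Delimiters are auto-detected between tab and comma; files mixing both are
  rejected. Duplicate feature or sample IDs, non-numeric cells, and invalid
  FASTA characters are hard errors naming the offender.
* −log₁₀(P) uses a 1e-300 floor; Clopper–Pearson intervals come from the
  beta quantile; a group whose pooled values are completely tied yields a
  degenerate rank-sum (P = 1).
* All times are integer days; no calendar-date parsing.
* Problem sizes used by the test suite and the acceptance script (e.g. 50
  simulation replicates for recovery rates, 10 for the reported summary
  rates, 1000 for type-I calibration, 50,000 permutations for the log-rank
  oracle) were chosen to make Monte-Carlo error small relative to the
  margins being tested while keeping the default runs quick on one CPU.

## Known limitations

* The stepwise procedure inherits the usual caveats of stepwise selection
  (post-selection inference is not corrected; reported AUCs are apparent).
* The exact log-rank branch enumerates label assignments and is limited to
  20 subjects; beyond that only the χ² approximation is offered.
* Probe summarisation beyond the explicit probe→gene map (e.g. averaging
  probes) is out of scope, as are platform normalisation, Cox regression,
  competing risks and k &gt; 2 log-rank.
* The Wilcoxon signed-rank paired comparison is provided for paired
  primary/metastasis designs without claiming equivalence to any particular
  published analysis, since such analyses rarely state their exact test.
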
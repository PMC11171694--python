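# Methods

## Scoring model

The package consumes per-core cell-detection tallies (viable tumor
cells, PD-L1-positive tumor cells, PD-L1-positive lymphocytes and
macrophages) as produced by whole-slide image-analysis software after
tissue classification and positive-cell detection. Image processing
itself is out of scope.

Scores follow the standard 22C3 pharmDx definitions: TPS is the
percentage of viable tumor cells with membranous positivity; CPS adds
positive immune cells to the numerator over the same tumor-cell
denominator and is capped at 100. Only *positive* immune cells enter —
neither score has an immune-cell denominator. Published methods
descriptions occasionally transpose the two formulas in print; the
implementation follows the assay definitions, which are the only ones
consistent with a capped CPS and with CPS ≥ TPS.

Quality control requires ≥ 100 viable tumor cells per core. Failing
cores are scored and reported with `qc_pass=False` for auditability but
excluded from lesion aggregation and all statistics. A lesion is the
arithmetic mean of its QC-passing cores; a single passing core carries
the lesion, zero passing cores exclude it. Scores are kept at full
precision internally and rounded to one decimal only in written reports.

Tri-categorical labels use half-open intervals with thresholds in the
upper class: CPS negative [0,1), low [1,20), high [20,100]; TPS
negative [0,1), low [1,50), high [50,100]. These are the cutoffs that
drive therapy selection (CPS ≥ 1 combination eligibility, CPS ≥ 20
monotherapy, TPS ≥ 50 second-line monotherapy).

## Heterogeneity analysis

*Intra-tumoral*: each lesion contributes two spatially separated cores;
the core with `sample_index` 1 is the reference (ties broken by lowest
`core_id`, logged). Lesions with more than two QC-passing cores use the
first two by sample index for the paired comparison, while aggregation
uses all passing cores. Lesions with fewer than two passing cores are
skipped with a logged count, not an error, so cohort denominators remain
visible. The 3×3 reference→comparison category table reports the
reclassification rate (off-diagonal fraction) plus a per-reference-row
breakdown (e.g. the fraction of reference-negative lesions upgraded to
low or high — the direction that would change treatment).

*Inter-tumoral*: patients possessing both lesion types enter; lesion
means are first averaged within type per patient (the design anticipates
multiple lesions per type; occurrences are logged). The reference type
is the primary tumor where present; swapping the types transposes the
counts. Absolute values are compared with a two-tailed Wilcoxon
signed-rank test; zero differences are dropped (Wilcoxon's convention),
and all-zero differences yield p = 1 with zero effective n rather than
an error.

*Test battery*: two unpaired groups → Mann–Whitney U; more →
Kruskal–Wallis followed by Dunn's post-hoc rank comparisons (pooled-rank
z statistics with tie correction, Bonferroni family adjustment, so
adjusted p ≥ unadjusted always); two paired groups → Wilcoxon; more →
Friedman. All tests are two-tailed; identical data yield p = 1 by
contract instead of raising. Correlations dispatch on data type:
Spearman's ρ (ratio), Kendall τ-b (ordinal), Phi (dichotomous, signed by
the 2×2 determinant, p from the uncorrected Pearson χ²). Every
correlation carries a Fisher r-to-z confidence interval when n ≥ 4; at
smaller n the interval is undefined and reported as NaN. Zero variance
in either vector produces an undefined-coefficient result with a note,
never an exception.

## Survival and associations

Overall survival runs from diagnosis; the headline analyses
administratively censor at 60 months ("5-year OS"): times are truncated
at the horizon and events beyond it become censorings, which can only
reduce the event count. Strata are score ≥ 1 vs < 1 on the lesion type
under study (patients lacking that lesion type are excluded).
Kaplan–Meier medians, the log-rank test, and the univariate Cox hazard
ratio at the same horizon form the per-lesion-type summary; site tables
(all HNSCC, oropharynx, oral cavity) add stage-adjusted and — for the
oropharynx, where p16 is observed — p16-adjusted models. UICC stage is
entered as ordinal I–IV (sub-stages collapsed); p16 maps
positive/negative → 1/0. Degenerate designs (single exposure level,
perfect exposure–covariate collinearity, non-convergence) are reported
as `status="failed"`, zero events as `status="no_events"`; neither
raises.

Treatment response uses RECIST dichotomized (CR/PR = response, SD/PD =
no response) and, because the radiochemotherapy subgroup is small, a
contingency coefficient C = √(χ²/(χ²+n)) on the binary-score × response
2×2 table instead of logistic regression. A zero margin leaves C
undefined (flagged).

## Synthetic cohort generator

The generator emulates the data structure the analyses assume: 200
patients by default, of whom ~84% contribute a primary tumor, ~27%
lymph-node metastases (LNM), ~13.5% local recurrences (LR) and ~4%
distant metastases (DM); patients whose inclusion draws produce no
lesion receive a primary. Each lesion has two cores of 100–2000 viable
tumor cells (3% of cores draw 20–99 cells and fail QC, exercising the
QC path).

Expression: a patient is structurally PD-L1-negative with probability
0.10; otherwise a latent tumor-positivity propensity p ~ Beta(0.65, 5.0)
is drawn. Lesion-type propensities couple through a Gaussian copula with
correlations chosen to hit target Spearman ρ of 0.5 (LNM) and 0.95 (DM)
with the primary (r_gauss = 2·sin(πρ/6)); recurrences draw an
independent propensity scaled by 0.6, reflecting lower post-treatment
expression. Within a lesion, each core's positive fraction is
Beta(p·κ, (1−p)·κ) with concentration κ = 25 (Beta-Binomial
overdispersion; κ = ∞ gives perfectly concordant cores); positive tumor
cells are Binomial, and positive immune cells Poisson with mean 30·θ per
100 tumor cells, so CPS exceeds TPS with realistic gaps.

These defaults were calibrated once, by simulation, against published
primary-tumor marginals for this tumor entity — ~72% CPS ≥ 1 and ~25.6%
CPS ≥ 20 at the lesion level, with ~29% intra-tumoral CPS
reclassification as a secondary target — and then frozen. Known
compromises of the zero-inflated-Beta family: the median primary CPS
lands near 7 (reported cohorts show ~4) and TPS ≥ 50 near 2% (vs ~6%);
matching all five exceedance/median constraints simultaneously is not
possible with this three-parameter shape, and the positivity and
high-expression fractions were prioritized. The generated Spearman ρ
between primary and LNM scores lands near 0.56 for the 0.5 copula
target because shared structural zeros add tied (0,0) pairs.

Survival is exponential within exposure group: the CPS-negative group
has median OS 22.7 months, and the patient's *realized* primary-lesion
CPS category (first available lesion type for patients without a
primary) multiplies the hazard by a true HR of 0.46. Censoring is a
uniform administrative window of 6–137 months, yielding roughly a third
censored observations. Clinical covariates (site, p16 within
oropharynx, T/N/UICC stage, grading, smoking, alcohol, treatment mix)
are drawn from fixed cohort frequencies, independent of expression and
of hazard; RECIST response is Bernoulli(0.5) for radiochemotherapy
patients only, independent of PD-L1 by design (the null the association
analysis should reproduce).

Reproducibility: one master seed feeds a `SeedSequence`; per-patient
streams are spawned from it, and survival uses a dedicated stream, so
cohorts are byte-identical across runs of the same configuration.

What passing tests on synthetic cohorts do *not* show: real cohorts have
spatially structured expression, covariate–expression correlations
(e.g. stage), non-exponential hazards, and informative censoring, none
of which the generator models. The generator validates the analysis
machinery and its statistical contracts, not biological conclusions.

## Problem sizes and numerical choices

Simulation-based tests use 200–260 patients per condition for
reclassification properties (≥ 200 lesion pairs per dispersion level),
2000 patients for hazard-ratio recovery (Monte-Carlo sd of the estimated
HR ≈ 0.03 around 0.46), 5000 for calibration marginals (binomial sd
≈ 0.7 pp), and ~4400 when ~1000 primary–LNM pairs are needed for
rank-correlation checks. The Kruskal–Wallis type-I-error check uses
2000 null replicates of 4×12 observations (3σ binomial band around 5%).

Ties in `sample_index` break by core id and are logged; Wilcoxon drops
zero differences; Dunn adjustment caps at 1; capping CPS happens after
the raw ratio is stored; category boundaries are evaluated with plain
comparisons (no epsilon), so a computed CPS of exactly 1.0 is "low" by
construction. Cox models with near-separation report infinite upper
confidence limits rather than failing.

## Limitations

- The generator's covariates are independent of expression and outcome;
  adjusted and unadjusted hazard ratios therefore coincide in
  expectation, unlike in observational cohorts.
- The per-cell input dialect expects one row per detected cell with a
  hard {Tumor, Immune, Stroma} classification; soft classifications or
  coordinate-level exports are not parsed.
- Fisher-z intervals for correlations are asymptotic and known to be
  liberal at very small n; they are reported for orientation, not
  inference, below n ≈ 10.
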
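# Methods

`qmpipe` implements a quantitative microbiota profiling (QMP) analysis for
longitudinal infant cohorts: absolute abundance estimation anchored on qPCR
total 16S loads, exposure-group construction from delivery records,
taxon-wise differential abundance with a count-model cascade, ordination
trajectories, and exposure → taxa → symptom path models. This note records
the models, the defaults that matter, and the choices made where the design
was genuinely open.

## Absolute profiling

Relative abundances are read proportions per sample. The uncorrected
absolute profile is

    copies(t, s) = rel(t, s) × load(s)        [16S copies / g feces]
    cells(t, s)  = copies(t, s) / c(t)        [cells / g feces]

where `load(s)` is the sample's qPCR total and `c(t)` the taxon's mean 16S
rRNA gene copy number. Copy numbers resolve by exact taxon match, then
nearest ancestor rank (family → order → class), then the global mean of the
copy-number table. By construction the uncorrected profile conserves the
qPCR load per sample to float precision; the test suite asserts 1e-9.

QC preceding profiling:

- **Blank subtraction.** Per sequencing run, the mean blank count of each
  taxon seen in that run's negative controls is subtracted from every sample
  of the run and floored at zero (a `max` variant is available). The
  operation marks the table's provenance and refuses re-application, since
  repeating the subtraction would corrupt counts. Runs without blanks pass
  through with a warning.
- **Rare-read filter.** Taxa below a configurable within-run total
  (typically 10–50 depending on run size) are zeroed per run.
- **Coverage cutoff.** Per-cohort minimum total reads (defaults 2000 for the
  main cohort, 120 for the low-biomass early-life cohort); the cutoff is
  inclusive — a sample at exactly the cutoff is retained — because only the
  threshold value, not the boundary convention, is conventionally reported.

## Exposure groups

Five study groups cross birth mode with intrapartum antibiotic class:
vaginal delivery without antibiotics (VD, the reference), cephalosporin or
penicillin exposure in vaginal delivery (VD-cep, VD-pen), and cesarean birth
with cephalosporin (CS-cep) or any other agent, combination, or unreported
class (CS-other). Elective and emergency sections are pooled. A cesarean
record without an antibiotic violates the cohort invariant (all sections
involved intrapartum prophylaxis) and raises; a vaginal delivery with an
agent outside the enumerated classes returns an explicit `unclassifiable`
label rather than being forced into a group or silently dropped. Samples
taken after an infant's first post-natal antibiotic course are censored from
all model fits, and infants treated before their first sample are dropped.

Adjustment covariates follow the cohort design: breastfeeding status
(exclusive reference), weeks since introduction of solids, probiotic
category, sequencing run, and protocol-modification flags. Constant or
aliased covariate columns at a timepoint are dropped with a logged note;
exposure dummies are never pruned.

## Differential abundance

Per timepoint and taxon, rounded absolute abundances are regressed on the
exposure factor plus covariates. The response is already load-anchored
(cells/g), so no additional total-load offset is used — an offset would
reintroduce the compositional normalisation the absolute scale removes.

The model cascade, in order: **negative binomial → Poisson → quasi-Poisson →
weighted least squares on log10 abundance**. Admissibility rules:

- NB is attempted when a one-sided Cameron–Trivedi score test finds real
  overdispersion (z > 1.645); otherwise the dispersion estimate is
  degenerate and the Poisson branch applies.
- NB estimation is a fast alternating scheme: a Poisson fit seeds the mean,
  the NB2 dispersion is estimated by method of moments from the residuals,
  and a fixed-dispersion NB GLM is refit (with one further dispersion update
  when the estimate moves by more than a factor of two). At tens of
  thousands of fits per simulation study this is orders of magnitude cheaper
  than joint MLE and yields equivalent Wald tests for the regression terms.
- **Dispersion sanity bound.** NB is only admissible when the (moderated)
  NB2 dispersion is at most 0.8. Beyond that the variation is essentially
  multiplicative (coefficient of variation near or above 100% at large
  means) and the Gaussian Wald tails of a count model are unreliable at
  cohort-scale group sizes; such taxa belong on the log scale, where the
  same variation is exactly additive.
- **Dispersion moderation.** In cohort-wide runs each taxon's dispersion
  estimate is moderated by the cohort median (`max(taxon, median)` over the
  tested taxa at that timepoint) before the gate and the fit. Without this,
  taxa whose dispersion estimate is low by sampling accident slip into the
  NB branch with understated standard errors and dominate the false
  discoveries — the same failure mode that motivates dispersion shrinkage
  in count-based expression tools.
- Every count-family fit must also pass a residual-spread diagnostic: a
  one-sided Spearman trend test of |Pearson residual| against the fitted
  mean at α = 0.05. A positive trend means variance grows faster than the
  family's variance function allows (heteroscedasticity), and the cascade
  falls through; after quasi-Poisson it lands on least squares of
  log10(y + 1) with group-wise inverse-variance weights (a two-stage
  OLS → WLS fit). The group variances are shrunk toward the pooled residual
  variance with 10 prior degrees of freedom before weighting: raw
  small-group variances treated as known weights understate the Wald tails.
- If every family errors out, the taxon is reported as NA with the collected
  reasons — never silently dropped.

Fold changes are back-transformed model coefficients (`exp` for log-link
families, `10**coef` for the log10-scale fallback) against the VD reference;
the display value is log10 fold change clipped to ±5. Raw group-mean ratios
are not used because coefficients are covariate-adjusted.

Only taxa present in strictly more than 30% of analyzed samples are tested.
Benjamini–Hochberg correction runs within one timepoint × contrast family —
the finest family consistent with reporting each contrast column separately;
this choice is deliberate and prominent because the correction family is
rarely stated in cohort reports. A result is significant when both P < .05
and q < 0.1.

## Ordination and trajectories

Profiles are log10(x + 1)-transformed; the distance between samples is
1 − Pearson r of the transformed vectors; classical scaling (PCoA, via
scikit-bio) embeds the samples. Correlation distances are generally
non-Euclidean: negative eigenvalues are zeroed and their summed magnitude
recorded in the result rather than being corrected away, so the user can see
how much structure the embedding discards. Constant sample vectors (zero
variance, undefined correlation) are excluded with a note.

Group differences at a timepoint are one-way ANOVAs on PC1 and PC2 scores,
reported per axis (a Bonferroni-doubled pooled P is also returned, since
"the first two coordinates" can be read either way). Groups with fewer than
two samples are excluded from the test.

Class-level developmental curves are local linear regressions of log10
abundance on age (tricube kernel; bandwidth a fixed fraction, default 0.5,
of the age range; evaluated on a fixed grid within 4–39 weeks). The display
band is the pointwise mean ± z[(1+level)/2] × SE of the local fit with
level 0.30 by default — a deliberately narrow "trend band" rather than a
95% inferential interval.

## Path (mediation) models

Per outcome and timepoint:

1. The outcome is regressed on birth mode (VD/CS) and antibiotic class
   (none/penicillin/cephalosporin) as separate factors, adjusted for feeding
   and probiotics, with the same NB scheme as above (Poisson fallback on
   non-convergence). Bounded visual-analog scores are treated as integer
   counts for the NB family; a Gaussian alternative is a switch.
2. Mediator taxa are selected by forward–backward stepwise search over
   standardized log10 abundances of prevalence-filtered genera, starting
   from the empty model. Two overfitting guards: model size is capped at
   n/10 predictors, and the per-parameter penalty is max(2, 2 ln m) for m
   candidate taxa (the risk-inflation criterion) instead of AIC's fixed 2.
   Plain AIC is demonstrably unsafe here: greedy best-of-m selection at
   n = 60 with 50 noise candidates manufactures models with median
   variance explained around 0.4, while the inflated penalty keeps the null
   median at 0 without costing power against a real mediator (a planted
   R² ≈ 0.3 chain survives the penalty with a large margin).
3. Variance explained is the squared Pearson correlation between fitted and
   observed outcome (comparable across NB and least-squares fits); a
   deviance pseudo-R² is emitted alongside.
4. Exposure → taxon edges are tested with the differential-abundance cascade
   on the selected taxa; edges are kept at P < .05 with their signs.
5. An exposure → outcome effect is labeled **mediated** when its direct term
   is significant alone (P < .05) but loses significance once the selected
   mediators enter the outcome model; it is **direct** when it survives
   them. This attenuation rule is an operational definition — path diagrams
   in the literature rarely define mediation numerically — and is not a
   formal natural-effects decomposition, which is out of scope.

## Synthetic cohort generator

The generator emulates the data such a study collects, with full
ground-truth bookkeeping. Default group sizes are the qPCR-quantified
subset (26/7/13/33/13 infants), default sampling ages 1, 4, 6, 12, 26, 39
and 52 weeks.

- **Abundances.** Log-normal per taxon with infant-level random intercepts
  (SD 0.8 on the natural-log scale — a free choice, documented here, since
  inter-infant correlation magnitudes are rarely reported) and residual SD
  0.7. Expected cells/g follow `load(age) × w_t × age^s_t`, copy-weighted
  normalised so the expected total 16S load tracks an age-increasing curve
  from 3×10⁹ at week 1 to 1.2×10¹¹ copies/g at one year. Exposure effects
  are natural-log fold changes applied within (group, week-window) cells.
- **Reads.** Cell abundances are inflated by taxon copy numbers *before*
  multinomial sampling (reads are amplicon copies), at a negative-binomial
  depth (mean 25 000, size 3). Contaminant taxa add Poisson reads to samples
  and are the only content of blank controls, so blank subtraction is exact
  in expectation.
- **qPCR.** The true value is the exact sum of copy abundances; measurement
  noise is multiplicative log-normal with CV 15% (triplicate-assay scale;
  no published error model exists, so the CV is configurable).
- **Outcomes.** Log-link linear predictors combine within-timepoint
  z-scores of mediator log abundances with direct exposure terms. Crying is
  a 0–100 visual-analog score via a scaled beta-binomial; defecation rate
  and symptom intensities are negative-binomial counts — matching the count
  models used downstream.
- **Discordant taxon.** `simulate_discordant_taxon` pins one taxon's
  expected absolute trajectory to slow growth (age^0.3) while the load curve
  grows strictly faster at every step, so its true relative abundance falls
  while its absolute abundance rises — the classic artifact that motivates
  absolute profiling.

What the generator does **not** emulate: taxonomic mis-annotation, chimeras,
primer bias, zero-inflation beyond multinomial sampling, infant-level
covariate confounding (covariates are drawn independently of group), or
realistic phylogenetic correlation between taxa. Passing recovery tests on
this generator therefore demonstrates correctness of the estimators under
the stated model, not robustness to annotation error or confounding in real
cohorts.

## Validation problem sizes

The benchmark suite uses single-timepoint cohorts sized to the questions
they answer: power at n = 25/group with a planted ln-fold-change of 1.5;
global-null error control over 200 replicates of 500-taxon, 50-sample
cohorts (group-only design); mediation recovery and null guards at n = 60
with 50 replicates each; masking with ten planted increases that jointly
dominate the community, so the exposed group's load roughly doubles and
proportion-scale effects shrink toward one. BH q values are checked against
a brute-force step-up implementation on 1000 random P-vectors, and PCoA
distances against a directly computed 1 − r matrix.

## Known limitations

- Fold changes from the NB branch are arithmetic-mean ratios; under heavy
  log-normal tails their sampling distribution is wide at n ≈ 25, which is
  visible in the power benchmark (~0.8, not 1, despite a large planted
  effect). The least-squares branch estimates geometric-mean ratios.
- The blank-subtraction rule ("corresponding numbers") is interpreted as
  per-run mean, unscaled by depth; a depth-proportional variant is not
  implemented, only a `max` summary.
- The mediation labels are associational; no causal identification is
  claimed.
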
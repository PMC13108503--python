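# Methods

`netseg` implements the analysis arc of a two-group resting-state fMRI study
of brain network system segregation (SS) and cognition: a synthetic cohort
generator, graph construction and thresholding, the SS metric, rank-based
group inference, correlation analyses with range-restriction correction,
bootstrap mediation, and a nested-CV classification comparison. This note
documents the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic cohorts can and cannot tell you about
real data.

## The segregation metric

For a binarized graph and a fixed ROI-to-network parcellation,

    SS = (Bw - Bb) / Bw

where `Bw` is the proportion of *possible* within-network ROI pairs that
survived thresholding and `Bb` the proportion of possible between-network
pairs. Globally, within-pairs are all pairs sharing a label; for a single
subnetwork, within-pairs lie inside that network and between-pairs bridge it
to every other network. SS is 1 when no between-network edge survives, 0
when connectivity is proportionally balanced, negative when between-network
connectivity dominates, and undefined when `Bw = 0` (recorded as missing and
excluded pairwise downstream — this arises at the sparsest thresholds on
small graphs, a case the metric itself does not address).

Graphs are built per subject as zero-lag Pearson correlations of the
concatenated runs (each run trimmed to TRs 5–200 by default, giving 392
volumes for two 200-volume runs), with negative correlations and the
diagonal set to zero. Proportional ("sparsity") thresholding at level *t*
retains the `round(t * P)` strongest positive weights, `P = N(N-1)/2` all
unique pairs (19,900 for 200 ROIs). Conventions chosen for reproducibility:

* the quota denominator is all unique pairs, not only positive ones — the
  natural reading of "the highest *t* of correlation coefficients"; the
  alternative (positive pairs only) would inflate edge counts on noisy data
  and is easy to obtain by pre-masking;
* quota rounding is half-away-from-zero (platform-stable, unlike banker's
  rounding);
* ties break by descending weight then ascending (row, column) pair index,
  so degenerate weights yield bit-identical graphs;
* negative weights are zeroed, not dropped, keeping matrix shape and
  denominators unambiguous.

Because the edge set at a smaller quota is a prefix of the edge set at a
larger quota under this tie-break, the full threshold sweep is computed from
one ranked ordering of the pairs via prefix sums; tests verify cell-by-cell
equality with explicit binarize-then-count calls and with an O(N²)
enumeration oracle.

## Synthetic cohorts

The generator emulates the statistical skeleton of a two-site aging study:
179 younger (18–34 y) and 117 older (60–89 y) adults, group-specific sex
(57.9% / 54.7% female) and site (15.1% / 29.1% site 2) compositions, and a
group-shifted log-normal head-motion percentage (log-mean 1.70 / 2.05,
log-SD 0.87 / 0.90, matching means near 8% and 11.6% with the older group
more variable).

Each subject carries a latent within-network correlation `rho_w` drawn from
a truncated normal — mean 0.45 (SD 0.05) in the younger group, mean 0.35
(SD 0.09) in the older group, truncated to `[rho_b + 0.01, 0.95]` — and a
shared between-network correlation `rho_b = 0.15`. The latent segregation

    g = (rho_w - rho_b) / rho_w

mirrors the SS formula so generative effect sizes are directly
interpretable. BOLD runs are i.i.d. draws from `N(0, R + sigma² I)` with
`R` the subject's block correlation matrix and `sigma = 0.3` white noise;
adding noise variance deflates all off-diagonal correlations by the same
factor `1/(1+sigma²)` and therefore leaves latent g exactly invariant. The
block matrix is checked for positive semi-definiteness and repaired by
eigenvalue clipping if numerically indefinite (compound-symmetric blocks
with `rho_w > rho_b >= 0` are PSD analytically, so repair only guards
degenerate configurations).

Cognitive composites are linear in (group, g, sex) plus Gaussian noise,
with defaults chosen to reproduce the study's qualitative structure on
roughly z-scored scales: executive declines with age and loads on g
(intercept 0.4, group −1.1, g 4.0, sex 0, residual SD 0.85); semantic
*improves* with age while loading positively on g (−0.3, +1.4, 4.0, −0.15,
0.85), so that measured SS acts as an inconsistent (suppression-style)
mediator; episodic declines with age but carries no g effect (0.3, −1.2,
0.0, +0.25, 0.85), a null-mediation control. Cognition is generated from
latent g, not from measured SS, so measured SS mediates group effects with
realistic attenuation. A 6% missing-at-random rate on each composite
reproduces the attrition from n = 296 to roughly n = 278 complete cases.

All randomness flows from one master seed through named substreams
(`cohort`, `timeseries`, `missing`, `bootstrap`, `folds`), so regenerating
one stage never perturbs another.

What the generator does **not** emulate: hemodynamic autocorrelation,
scanner drift, per-pair heterogeneity of correlations within a block,
site-specific acquisition effects, or run-to-run within-subject state
changes (runs are i.i.d. — the studies this emulates do not characterize
run-to-run variability, so no attempt is made to model it). A consequence
of homogeneous blocks is that measured SS saturates near 1 at sparse
thresholds in the younger group (within- and between-block correlation
distributions barely overlap); group differences are still recovered
because the older group's lower, more variable `rho_w` produces graded
overlap. Passing recovery tests therefore demonstrate that the estimators
detect effects *of the assumed generative form*, not that real fMRI data
meet those assumptions.

## Inference conventions

* **Gates.** Levene (Brown–Forsythe, median-centered) and Shapiro–Wilk act
  only as gates motivating rank-based procedures, mirroring the analysis
  plan they support.
* **Rank ANOVA.** The outcome is mid-ranked over the listwise-complete
  sample and fit by an additive linear model on group + sex; the reported F
  is the type II main effect of group — for the additive model, the partial
  F against the no-group model — with df (1, n − 3). Type II is
  order-invariant for main effects and matches the reported df convention.
* **Spearman partials** residualize mid-ranked x and y on mid-ranked
  covariates and correlate the residuals; p from the t approximation with
  df = n − 2 − k. Verified against an independent implementation
  (pingouin) to 1e−10.
* **Robust check.** Huber M-estimation (tuning constant 1.345, IRLS, max 50
  iterations, tol 1e−8) via statsmodels RLM, reported alongside — not in
  place of — the rank tests.
* **Sweep-level conclusions** are drawn only through the consistency rule:
  an effect is declared only when significant at ≥ 3 of the 10 thresholds
  (0.05–0.50 in steps of 0.05) at α = 0.05. No further multiplicity
  correction is applied, by design.
* **Demographics.** Uncorrected Pearson chi-squares for 2×2 tables
  (continuity correction available but off by default); race/ethnicity
  tables exclude "not provided" rows. Mann–Whitney U with mid-rank tie
  handling for ordinal/heteroscedastic variables.
* **Composites.** Each test is z-scored over the full analysis sample (not
  within group — within-group scaling would erase the group differences the
  composites are meant to carry), sign-flipped for inverse-oriented tests
  (e.g. completion times), missing entries imputed with the age-group mean
  of that test's z-scores, then averaged. Zero-variance tests contribute 0
  and are logged.

## Range-restriction correction

Thorndike's Case II for direct selection on x:
`r_adj = r·u / sqrt(1 − r² + r²u²)`, `u = S/s` with `S` the pooled
(df-weighted across both groups) SD standing in for the population SD and
`s` the restricted group's SD. Adjusted significance uses the ordinary t
approximation at the restricted sample's n — conservative, since the
correction itself adds no information. For outcomes restricted on both
variables, a two-stage scheme applies Case II sequentially for the x and
then the y ratio; no closed-form bivariate correction is assumed, and the
scheme is validated purely against Monte-Carlo selection simulations
(double middle-selection on bivariate normal data), where it moves the
estimate toward the population value in ≥ 90% of runs. The stage order is
immaterial to first order and the scheme is isolated behind one function so
it can be swapped.

## Mediation

Model-4 mediation of the binary age-group effect on a cognitive index
through global SS at one threshold, with sex and group-relative age
(`(age − group min)/group range`, a within-group age covariate in [0, 1])
as covariates. Three OLS fits on the listwise-complete sample give a, (b,
c′) and c; the decomposition `c = c′ + a·b` then holds exactly and is
asserted to 1e−10. The indirect effect's CI is a percentile bootstrap over
subjects (with replacement, unstratified, default 5,000 resamples at 95%);
percentile rather than bias-corrected intervals are the default because
they are the simpler, assumption-lighter choice — the BC variant would be a
one-line change in the quantile step and the choice is recorded in the
output. Bootstrap resamples in which X is constant (vanishing probability
at study sizes) are redrawn. Standardization is partial: M and Y are scaled
to unit SD on the analysis sample, X stays binary, so standardized effects
read as SD-units-per-group-switch. Classification of the result: classical
when the CI excludes 0 and the indirect effect shares the direct effect's
sign; inconsistent when the CI excludes 0 with opposite sign (the mediated
path attenuates the total effect); none otherwise.

## Classification comparison

Two L2 logistic regressions — cognition-only vs cognition plus global SS
across the threshold grid — share one stratified 70/30 split and identical
stratified outer folds (5 by default). The split and folds derive from
labels and the seed only, never from features. The inner loop (5-fold)
selects the penalty from 13 log-spaced values in 10⁻³…10³ by mean
validation AUC (the selection metric is a free choice; AUC matches the
headline metric). Features are standardized inside each training portion
only. Outer-fold AUC/accuracy/balanced accuracy are compared by two-sided
paired t across the shared folds; a final model per feature set is refit on
the full training portion and scored once on the held-out 30%. Degenerate
paired comparisons are reported explicitly: an all-zero fold-wise
difference (self-comparison) is non-significant by convention (p = 1), an
exactly constant nonzero difference is unbounded evidence (p = 0).

## Numerical and degenerate-input conventions

Mid-ranks for all ties. Exact symmetry of weight matrices is enforced (the
elementwise minimum of W and Wᵀ guards against floating-point asymmetry
from the correlation step). Constant outcomes, zero-variance groups, zero
table margins, non-binary X, collinear covariates and out-of-bounds ages
raise errors rather than returning NaNs. Undefined SS cells propagate as
missing. RLM non-convergence within 50 iterations is flagged in the output
table rather than raised.

## Problem sizes used in validation

The validation suites run at sizes chosen to make their Monte-Carlo bounds
sharp while staying cheap: group-difference recovery uses 100 full-size
default cohorts (n = 296, 200 ROIs, two 200-volume runs each); mediation
recovery uses 200 cohorts of n = 278 with 1,000 bootstrap resamples (the
point estimate and identity do not depend on the resample count);
calibration uses 1,000 null rank ANOVAs at n = 296 and 500 null paired
comparisons; the exchangeable-graph null uses 200 replicates of 200-ROI
graphs; range-restriction recovery uses 40 replicates at n = 10,000. The
default parcellation ships as a generated table following the standard
7-network naming with realistic per-network sizes; analyses of real data
should load the atlas's own membership table.

## Known limitations

* The homogeneous-block generator makes SS distributions more saturated
  and less heavy-tailed than real cohorts; threshold-specific behaviour
  near saturation (ties at SS = 1) leans on the rank procedures' mid-rank
  handling.
* The bivariate range-restriction scheme is a pragmatic sequential
  correction, not a derivation; it is validated only against its own
  selection simulations.
* Group-relative age is computed from the observed group min/range when not
  supplied, which makes it sample-dependent at small n.
* The pipeline's caching keys on the config hash and seed; editing outputs
  by hand invalidates nothing.
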
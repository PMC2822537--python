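# Methods

## Data model and normalization

Expression is a probes × samples matrix of log-scale intensities
(`ExpressionMatrix`), complete (no missing values; incomplete matrices
are rejected rather than imputed).  The log base defaults to 2, the
Affymetrix convention; the base only shifts/scales all values jointly
and affects no correlation, rank or grouping statistic.
`normalize_mean_scale` applies the classical microarray convention of
scaling the grand mean to log(500): a single additive shift on the log
scale (equivalently one multiplicative factor on linear intensities).
A multiplicative-pre-log variant would differ only by the same class of
monotone transforms and was not implemented.

Genomic intervals are 0-based half-open internally; BED6 is ingested
as-is, GFF3 (1-based closed) is converted at the parser boundary.
Clinical records carry disease-free survival time (any consistent unit;
months in the simulations), a 0/1 event indicator and a grade label.

## Architecture detection

A sense-antisense gene pair is any opposite-strand pair with interval
intersection ≥ 1 bp (configurable).  Orientation: *embedded* when one
interval contains the other; otherwise *convergent* when the plus-strand
gene lies 5′ of the minus-strand gene (the overlap covers both 3′ ends)
and *divergent* when the minus-strand gene lies 5′ (overlap covers both
5′ ends).  Architectures are connected components of the pair graph
(networkx), ordered by leftmost coordinate.

Real loci sometimes recruit a member without any overlap, through a
shared bidirectional promoter.  `promoter_edges` optionally links a
minus-strand gene whose 5′ end faces the 5′ start of a downstream
plus-strand gene across ≤ 1 kb (default; configurable).  The strict
overlap definition stays the default — promoter edges are additive and
marked `divergent_promoter` so provenance is never lost.

Neighbour windows collect non-member genes whose intervals lie within a
distance bound (default 200 kb, wide enough to cover both an ~80 kb
centromeric and an ~170 kb telomeric flank) of the architecture's span,
split upstream/downstream.

## Cluster significance: bootstrap Bartlett

For p module genes with sample correlation matrix R and N samples,

    T = -(N - 1 - (2p + 5)/6) · ln|R|,  df = p(p-1)/2,

is asymptotically χ²(df) under H₀: R = I.  The analytic P is the upper
tail.  Because physically neighbouring genes co-express through shared
chromatin domains, the analytic null flatters a *local-cluster* claim;
the bootstrap null draws B = 5,000 (default) windows of p consecutive
probes in genomic row order from the full expression pool, excluding
windows that intersect the target set, and reports
p_boot = #(T_b ≥ T)/B (resolution 1/B).  Singular windows are redrawn,
capped at 10·B attempts.  Measured behaviour (acceptance script):
analytic type-I error 0.006–0.015 at α = 0.01 over 2,000 null cohorts
(N = 250, p = 5); bootstrap null P uniform (KS); power 1.0 on planted
ρ = 0.9 blocks at N = 200.

## Matrix comparison: Box's M

The hypotheses concern correlation structure, while M is defined through
covariance determinants, so each group's variables are standardized
(mean 0, variance 1, per group) first, making the compared covariances
equal the correlation matrices:

    M = (v1 + v2) ln|S_pool| - v1 ln|S1| - v2 ln|S2|,
    S_pool = (v1 S1 + v2 S2)/(v1 + v2),   v_i = n_i - 1.

Significance uses Box's χ² approximation (two groups: scale 1 − c₁,
df = q(q+1)/2); the F variant is not implemented.  Standardization makes
the test conservative (diagonals are pinned), which the calibration runs
confirm — null pass rate ~1.0 at α = 0.01 — while power at ρ = 0 vs 0.7,
n = 150, is ~1.0.  For unequal dimensions (module p vs neighbours
q > p), all C(q, p) order-preserving neighbour sub-signatures are each
compared with the module and the arithmetic mean of the P values is
reported alongside the count; order-preserving enumeration keeps the
sub-signatures genomically meaningful.

Grade-stratified matrices skip strata with fewer than p + 2 samples
(warning).  Pearson is used when n ≥ 50 and the Kolmogorov-Smirnov/
Lilliefors screen (statsmodels) passes at α = 1%; Kendall tau-b
otherwise (tau-b for tie robustness).

## Survival: data-driven grouping

**1D.** Candidate cut-offs are midpoints of consecutive distinct
expression values; admissible candidates keep ≥ 10% of patients and ≥ 3
events on each side (defaults; the minimum a stable two-group Cox fit
needs).  The cut-off maximizing the two-sample log-rank statistic wins;
exact ties go to the candidate nearest the median.  The log-rank scan is
vectorized over candidates (suffix-sum risk counts), so a full scan
costs about one matrix pass.  The resulting grouping is fitted with a
univariate Cox model for a binary covariate, coded directly as Newton
iteration on the Breslow-tie partial likelihood (the binary case has
closed-form derivatives; lifelines' Efron-tie fitter serves as an
independent cross-check on tie-free data, where the conventions
coincide).  The Wald P is the two-sided normal tail of β/se(β).
Monotone likelihoods (a group separating all events) raise a
convergence error rather than returning a divergent β.

**2D.** With the two 1D cut-offs fixed (never re-optimized), patients
fall into quadrants A (low/low), B (high/low), C (low/high),
D (high/high).  The seven non-trivial two-group designs over the
quadrants are {A}, {B}, {C}, {D}, {A,D} vs the rest (synergistic) and
{A,C} | {B,D}, {A,B} | {C,D} (independent — exactly the single-gene
splits).  The design numbering 1–7 in that order is this package's
canonical convention.  Each admissible design (same size/event minima
per side) is Cox-fitted; the best design is the smallest Wald P.  A pair
is *synergistic* when its best P is > 10× smaller than both single-gene
P values (strict inequality).

**Screening and FDR.** Gene and pair families are corrected separately
with Benjamini-Hochberg step-up (statsmodels backend), valid under
positive dependence; the data-dependent threshold (largest significant
raw P) is reported.  The per-gene P of an *optimized* cut-off is
anti-conservative — the scan takes a maximum over ~n candidates — so by
default (the historical convention for this analysis) the screen uses
the raw Wald P and its FDR calls should be read as a ranking.  For
calibrated screening, `correct_selection_bias=True` replaces the
screening P with the Miller–Siegmund improved-Bonferroni P for the
maximally selected log-rank statistic over the realized candidate
quantile range; under a global null this brings the significant fraction
to ≈ 0.01 at α = 0.05 (measured over 500 screens), where the raw-P
screen shows ≈ 0.17.  A closed-form correction was chosen over a
permutation correction for runtime; the permutation route can be built
on `find_cutoff_1d` directly if exactness matters.

Two-cohort designs are emulated by two independent seeds;
`intersect_pair_screens` keeps the significant pairs common to both, the
replication filter used in practice.

## Copy number

Kendall tau-b between each (probe, marker) pair across ≥ 8 shared
samples, with an α = 1% mask for the report view.  Identical marker
columns (common inside one amplified segment) are deduplicated with a
warning.  Normalization divides linear-scale expression by the
per-sample copy number at a marker and re-logs — ``y − log₂(cn)`` — so a
purely dosage-driven correlation pattern collapses while
regulation-driven structure survives.

## Synthetic data

The generator plants exactly the structure the analysis assumes:

* **Expression** — p = 5 module genes from an equicorrelated normal
  (single shared factor for ρ ≥ 0, recorded in the truth record;
  default ρ = 0.6, optionally per grade to emulate grade-dependent
  tightening), q = 6 independent neighbours, and a 2,000-probe
  independent background pool, laid out in genomic row order with the
  module mid-pool; grand mean scaled to log₂(500).
* **Layout** — five genes in two convergent overlaps (500 bp and
  exactly 376 bp) chained by two < 1 kb bidirectional-promoter gaps,
  flanked by neighbours within 80 kb (centromeric) / 170 kb (telomeric)
  and one far gene beyond any default window.
* **Survival** — exponential event times, baseline hazard 0.02 per
  month (median ≈ 35 months untreated), hazard ratio attached to the
  dichotomized module factor (default 2.5), censoring from a calibrated
  Uniform(0, U) so the expected censored fraction hits the target
  (default 30%).  `driver_hr_for_gene_hr` converts a desired
  *gene-level* median-split hazard ratio into the driver-level one via
  the bivariate-normal quadrant-agreement mixture (e.g. gene-level 2.5
  at ρ = 0.6 requires driver 7.32; realized gene-level HR measured
  2.49).
* **Copy number** — markers share one latent amplification factor with
  cn = 2·2^(w·amp), w = sin(πτ/2) chosen analytically so the Kendall
  correlation with module expression hits the target τ (default panel:
  38 samples, τ = 0.4); log₂(cn) equals the dosage component of module
  expression exactly, which is what makes the normalization property
  exact rather than approximate.

Cohort sizes default to 251 (and 159 for a second cohort), matching
typical breast-cancer microarray cohorts.  The generator does **not**
emulate probe-level noise models, batch effects, non-proportional
hazards, heavy-tailed expression or missing values — so passing tests
demonstrate correctness of the statistics under their own assumptions,
not robustness to real-data pathologies.

## Numerical choices and degenerate inputs

Newton steps are damped to ±2 per iteration; |β| > 30 is treated as
monotone-likelihood divergence.  Log-rank variance terms with one
patient at risk are zeroed.  Constant probes, singular correlation or
covariance matrices, all-censored cohorts, groups without events, and
inadmissible cut-offs all raise errors naming the offender rather than
returning NaNs; inside the batch screen such probes become NaN rows
excluded from FDR.  Bootstrap resolution is 1/B; p_boot = 0 means
"below 1/B".

## Problem sizes in the validation runs

The acceptance script and heavy tests use: 2,000 null cohorts for
Bartlett calibration (N = 250, p = 5); 200 repetitions × B = 500 for
bootstrap uniformity; 200 repetitions for Box's M calibration and power
(n = 150); 100 repetitions for cut-off (K = 200) and design (K = 300)
recovery; 500 null and 100 planted screens (11 probes, n = 150/251);
20 repetitions for the copy-number property (n = 38).  These sizes give
binomial standard errors of 1–4 percentage points on the reported rates.

## Known limitations

* The Box's M χ² approximation degrades for p close to n; the F
  approximation is not implemented.
* The maxstat correction is a tail bound — slightly conservative, and
  approximate below |z| ≈ 1.
* Proportional hazards is assumed, not tested; no multivariate Cox with
  clinical covariates.
* Transcript-isoform-level overlap resolution is out of scope; gene
  models are treated as single intervals.
* The seven-design numbering is canonical to this package; other
  implementations may index the same partitions differently.
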
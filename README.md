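# sagpipe

Statistical analysis of **sense-antisense gene architectures** and their
clinical relevance, for computational biologists working with microarray
expression cohorts, survival annotation and SNP copy-number data.

Some mammalian genes overlap on opposite DNA strands.  Two such genes form
a *sense-antisense gene pair* (SAGP); when overlapping pairs share genes
(directly or through a bidirectional promoter) they chain into a *complex
sense-antisense gene architecture* (CSAGA).  `sagpipe` asks, for a
candidate architecture found in strand-aware gene models:

1. **Do its genes co-express as a cluster?** The Pearson (or, for small
   samples, Kendall tau-b) correlation matrix *R* of the *p* member genes
   is tested against H₀: *R* = *I* with Bartlett's sphericity statistic

   *T* = −(*N* − 1 − (2*p* + 5)/6) · ln|*R*|,   df = *p*(*p* − 1)/2,

   compared both against its asymptotic χ² distribution and against an
   empirical null built from *B* = 5,000 random windows of *p*
   physically neighbouring genes — neighbouring genes share chromatin
   domains, so this bootstrap null is the honest reference for a "does
   this local cluster stand out" question.

2. **Is the cluster distinct from its genomic neighbours, and does it
   change with tumour grade?** Box's M test on per-group standardized
   data compares two correlation structures; matrices of unequal
   dimension (a *p*-gene module vs *q* > *p* neighbours) are compared by
   averaging the P values over all C(*q*, *p*) order-preserving
   sub-signatures.

3. **Do its genes, singly or in pairs, predict disease-free survival?**
   One-dimensional *data-driven grouping* (DDg) dichotomizes patients at
   the expression cut-off *c* maximizing the Kaplan-Meier curve
   separation (two-sample log-rank), then fits a univariate Cox
   proportional-hazards model to the grouping (Breslow ties, Wald P).
   Two-dimensional DDg splits the joint expression plane of a gene pair
   into quadrants A-D at the two 1D cut-offs and evaluates the seven
   two-group designs over the quadrants — five "synergistic" and two
   "independent" (the single-gene splits) — keeping the design with the
   smallest Wald P.  Gene and pair families are corrected with
   Benjamini-Hochberg FDR; a pair whose best P beats both individual
   gene P values more than ten-fold is flagged *synergistic*.

4. **Is the co-expression just DNA dosage?** Kendall tau-b between
   per-marker copy number and expression identifies amplification-driven
   genes; dividing linear-scale expression by copy number and re-testing
   shows whether the cluster survives dosage normalization.

A synthetic-data generator emits cohorts with exactly this structure
(planted module, genomic layout, exponential survival, amplification
track) plus a machine-readable truth record, so the entire pipeline is
testable offline.

## Worked example

```python
from sagpipe import (SimulationConfig, gen_cohort_bundle, detect_sagps,
                     chain_csagas, promoter_edges, bootstrap_bartlett,
                     DataDrivenGrouping, PairedDataDrivenGrouping)

cfg = SimulationConfig(n_samples=251, pool_size=2000, rho=0.6,
                       hazard_ratio=3.0, censoring_rate=0.3, seed=42)
b = gen_cohort_bundle(cfg)
expr, clin, genes = b["expression"], b["clinical"], b["gene_models"]

pairs = detect_sagps(genes)
for p in pairs:
    print(f"{p.gene_a}-{p.gene_b}: {p.orientation}, {p.overlap_len} bp")
print("CSAGA members:",
      chain_csagas(pairs, genes, extra_edges=promoter_edges(genes))[0].member_genes)

print(bootstrap_bartlett(b["truth"]["module_probes"], expr,
                         B=5000, seed=1).summary())
print(DataDrivenGrouping.from_expression(expr, "MOD3", clin).fit().summary())
print(PairedDataDrivenGrouping.from_expression(expr, "MOD3", "MOD4", clin)
      .fit().summary())
```

prints

```
MOD1-MOD2: convergent, 500 bp
MOD3-MOD4: convergent, 376 bp
CSAGA members: ['MOD1', 'MOD2', 'MOD3', 'MOD4', 'MOD5']
Bartlett test of sphericity (H0: R = I)
  T = 658.2428  df = 10  N = 251  p = 5
  analytic P (chi-square upper tail) = 5.740e-135
  bootstrap P (5000 neighbouring-gene draws) = 0
1D data-driven grouping for probe MOD3
  cut-off = 9.7200 (log-rank chi2 = 21.513, 200 admissible candidates)
  groups: low n=187 (117 events), high n=64 (51 events)
  Cox PH (binary group, Breslow): beta = 0.7721 (HR = 2.164), se = 0.1704, z = 4.530, Wald P = 5.901e-06, n = 251, events = 168
2D DDg pair (MOD3, MOD4): best design 6 {AC}|{BD} (independent), pair P = 5.901e-06, individual P = (5.901e-06, 1.326e-04), synergy = False
```

Reading: the two convergent overlaps (one of 376 bp) chain into a
five-gene architecture via bidirectional-promoter links; the module's
correlation matrix is overwhelmingly non-spherical even against the
neighbouring-gene null; gene `MOD3` splits the cohort into a 64-patient
high-risk group with hazard ratio 2.2; for the pair (`MOD3`, `MOD4`) the
best grouping is the plain single-gene split (design 6), so no synergy is
claimed.

The same stages are exposed as a CLI — `sagpipe simulate`,
`detect-architecture`, `corr-test`, `compare-matrices`, `ddg1d`, `ddg2d`,
`cn-correlate` and `run-all` (full pipeline from a YAML config, writing
one TSV report per stage with a seed/config-hash header).

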
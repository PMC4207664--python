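# Methods

## What the package computes

`vcqtl` maps quantitative trait loci that control the *dispersion* of
phenotypes rather than (or in addition to) their means, in a biparental
line cross genotyped at two homozygote classes per marker:

1. **Single-trait variance QTL (genetic canalization).** At every marker the
   families are split by homozygote class and compared with the
   Brown-Forsythe statistic — the one-way ANOVA F computed on absolute
   deviations from each class median, `z_ij = |y_ij − median_i|`. The
   median-centred form keeps the test calibrated under skewed and
   heavy-tailed trait distributions, which season-structured flowering data
   are.
2. **Multi-trait covariance-structure QTL (genetic constraint, GxE).** Per
   marker, within-class covariance matrices `G_CO`, `G_MT` of family-mean
   trait vectors are compared by
   - *size*: a trace-form Box's M, `M = N·ln S − Σ V_i·ln S_i` with
     `S_i = trace(G_i)`, `V_i = n_i − 1`, and `S` the df-weighted pooled
     trace. `M ≥ 0`, equals 0 iff the traces agree, and is invariant to a
     common rescaling. (A classical determinant-based Box's M is available
     via `boxs_m(..., form="det")` for comparison; the trace form is the
     scan default.)
   - *orientation*: the angle between leading eigenvectors, folded into
     `[0, π/2]` because eigenvectors are axes (an arccos above π/2 is
     reflected to π − θ);
   - *subspace overlap*: the Krzanowski index, the sum of eigenvalues of
     `S = AᵀBBᵀA` for the first-`k` eigenvector bases of the two matrices
     (equivalently `‖BᵀA‖²_F`), in `[0, k]`, with `k ≤ ⌊p/2⌋` (default
     `⌊p/2⌋`). The scan uses the *negative* index so that for every method a
     larger statistic means more dissimilar matrices. For two traits the
     G_max angle already captures all orientation difference, so the
     Krzanowski scan requires at least four traits.
3. **Genome-wide significance** for all scans comes from one shared
   maximum-statistic permutation null per scan: family phenotype rows
   (whole trait vectors, preserving inter-trait correlation) are shuffled
   against the genotype matrix; each permutation contributes its
   genome-wide maximum statistic; a marker's p-value is the fraction of
   maxima that reach or exceed its observed statistic. Ties count as
   exceeding (conservative), and the observed scan is *not* counted among
   the permutations by default, so p = 0 is a reportable value; an
   `add_one` mode gives the (n≥ + 1)/(n_perm + 1) estimator instead.
4. **Variance decomposition at a locus.** With class frequencies p, q,
   means μ₁, μ₂ and SDs σ₁, σ₂, the pooled trait variance splits exactly as
   `Vp = pq(μ₁−μ₂)² + pq(σ₁−σ₂)² + (pσ₁+qσ₂)²` — the mean-difference share
   (Vm), the variance-difference share (Vv) and a remainder. Vm = 0 iff the
   class means agree and Vv = 0 iff the class SDs agree. Sample moments
   (ddof = 1) are plugged in.
5. **HIF mixed models.** REML linear mixed models for heterogeneous-
   inbred-family experiments (fixed genotype × background interaction tests
   with random family and block intercepts), a qPCR ΔCt expression model,
   and the bud/expression association (below).

## Marker and trait preprocessing

Traits are standardized per column to mean 0, SD 1 (sample SD) before any
scan; missing family means are preserved and dropped pairwise downstream
(single-trait scans drop a family only for that trait; covariance scans use
complete cases over the trait set, since a covariance needs full vectors).
Markers with minor homozygote-class frequency below 0.33 (over non-missing
calls) are removed before scanning: segregation-distorted markers give one
tiny class and unstable (co)variance estimates. Parental lines, when
flagged in the phenotype table, are excluded from scans, which contrast
classes among the recombinant families. Heterozygous genotype calls are
coerced to missing on read — the scans are two-class contrasts.

## The threshold/sigmoid flowering simulator

The synthetic module generates data with the structure these scans assume,
for testing and power analysis. The generative picture: flowering is gated
by a signal integrator whose activation probability is
`y = 1/(1 + exp(a(−x + b_G)))`, where the input signal
`x = Σ β_m·(allele dose at background locus m) + E_env + N(0, noise_sd)`
accumulates small background-locus and environment contributions, and the
threshold `b_G` depends on the genotype at one focal major locus
(`b_MT = 0 < b_CO = 2.2` in signal units; the early-flowering class has the
lower threshold). With probability `y` an individual flowers in season one
at `season1_base − slope_c·x` days (+noise, truncated below the 180-day
season boundary); otherwise it flowers in season two at `season2_base`
(+noise, above the boundary). Leaf number at flowering is proportional to
flowering day plus noise. Family means over `n_reps_per_family = 5`
siblings are returned.

Defaults and why:

| parameter | default | role |
|---|---|---|
| `a` | 15 /signal-unit | steep, near-threshold gating; the large-`a` limit is a hard threshold |
| `b_CO`, `b_MT` | 2.2, 0.0 | threshold separation ≈ 2.5 among-family signal SDs, so an environment can straddle one threshold at a time |
| background loci | 12 loci, β = 0.5, spread over non-focal linkage groups | among-family signal SD ≈ 0.87; equal effects keep the threshold picture clean |
| `noise_sd` | 0.3 | within-family signal noise |
| `season1_base`, `season2_base` | 150, 260 days | bimodal seasons separated at 180 days |
| `slope_c` | 3 days/signal-unit | background loci act as ordinary mean-QTL within a season |
| environment offsets | +2.6/+3.0 (promoting), −0.4/−0.15 (slightly inhibiting), −3.0/−2.7 (strongly inhibiting) | see below |

The six environment offsets are a packaged calibration, not a fit: in the
two promoting chambers the signal saturates above both thresholds (no
variance difference between focal classes); in the slightly inhibiting
chambers the signal straddles only the high threshold (the high-threshold
class splits across seasons → its among-family variance is larger); in the
strongly inhibiting chambers it straddles only the low threshold (the
high-threshold class is uniformly deferred to season two and is now the
*canalized* one) — i.e. the direction of the canalization effect reverses
between environments. Simulated grand-mean flowering times land at roughly
132, 155 and 230 days in the three environment categories.

RIL genotypes are simulated by five generations of selfing from a fully
heterozygous F1, with crossovers drawn independently per meiosis under the
Haldane map function (no interference — the simplest standard choice).
Residual heterozygotes (expected fraction 2⁻⁵ ≈ 3.1%) are recorded as
missing, exactly as heterozygous calls are treated on data read-in. The
default map is 164 markers in 7 linkage groups at 5.5 cM spacing; the
default panel is 178 families.

The HIF generator fixes one background signal level per HIF (families get
small deviations, held fixed across siblings; blocks get day-scale
deviations) and splits families evenly between the focal homozygotes. A
true genotype-by-background interaction on flowering exists exactly when
the HIF background levels straddle one threshold. The expression generator
maps the sigmoid response to ΔCt = −9 + 4·y plus family and plant noise
(negative regime), and draws visible-bud status with probability y, so bud
presence and expression are associated by construction.

What the simulator does *not* emulate: linkage disequilibrium beyond the
Haldane model (no crossover interference, no segregation distortion), any
second-vernalization bookkeeping (the excluded cold period is simply never
added), a separate distribution for chamber moves within season two,
non-flowering individuals (everyone flowers by season two), and
environment-specific leaf-number couplings. Passing tests on these data
demonstrate calibration and power of the statistics under the assumed
threshold mechanism, not the realism of any particular chamber.

## HIF mixed models: fitting and testing

The models are `response ~ genotype * HIF` (fixed) plus independent random
intercepts for family and, where present, block. REML estimates maximise
the restricted likelihood profiled over the error variance, parameterised
by the variance ratios γ_t = σ_t²/σ_e²; all linear algebra is done in a
low-rank (Woodbury) form on the q × q random-level cross-products, and
every zero-boundary subset of components is checked explicitly, so boundary
estimates are exact zeros. (statsmodels' MixedLM was not used for this
layout: on crossed variance components in a single group it can report
convergence at a restricted likelihood far below the true optimum; the
in-package fit agrees with lme4/lmerTest to ~6 significant figures, which a
test enforces via Rscript.)

Fixed terms are tested with marginal (Type III) Wald F in sum-to-zero
coding. Denominator df follow the containment idea: a term whose factors
are contained in a random effect's declared factor set is tested at that
random effect's df (its rank contribution beyond the fixed design), others
at the residual df `N − rank([X Z])`. Family is declared nested in HIF for
the phenotype model (HIF tested at the family level; genotype and
interaction at the residual level) and nested in genotype × HIF for the
expression model (all fixed terms at the family level, matching the small
crossed design with two plants per family). A Satterthwaite-style
approximation is deliberately not implemented; with the F statistics
unaffected by the df choice, containment keeps the table reproducible.

Random effects are tested by likelihood-ratio χ² (1 df) between REML fits
with and without the component, both evaluated on the same closed-form
restricted-likelihood scale. The 1-df reference is anticonservative at the
zero boundary (the usual 50:50 mixture argument); this is the conventional
reporting and is documented rather than corrected. A component estimated at
zero yields χ² = 0, p = 1.

ΔCt is reference-gene Ct minus target Ct; the analysis response is ΔCt
itself, not 2^ΔCt, whose distribution across samples is log-skewed. A Holm
(sequential Bonferroni) utility is provided for multi-trait summaries.

## Numerical choices and degenerate inputs

* Brown-Forsythe with all within-class median deviations zero raises a
  degenerate-statistic error in the scalar API; inside vectorised scans the
  convention is F = ∞ when the between-class part is positive, 0 otherwise.
* A genotype class with fewer than 2 (variance scan) or 3 (covariance scan)
  usable families skips the marker with a warning.
* Eigenvector sign and order: `numpy.linalg.eigh` ordering with the
  largest-magnitude component made positive where a direction is exposed;
  all reported statistics (angle after folding, Krzanowski index, Box's M)
  are invariant to eigenvector sign.
* Permutations draw from `numpy.random.default_rng(seed)`; one master seed
  per scan determines the whole permutation block, so scans are exactly
  reproducible.
* A constant mixed-model response returns F = 0 for every fixed term.

## Monte-Carlo sizes in the validation suite

The statistical validation suite uses: 1000 random instances for the
Brown-Forsythe/Levene oracle agreement and 200 for the Krzanowski oracle;
200 null scans × 1000 permutations each for the family-wise error
calibration of the variance and Box's M scans; 100 seeds × 1000
permutations for planted variance-QTL recovery; 50 seeds per scenario for
the size-only/rotation-only covariance perturbations (the rotation
scenario plants *anisotropic* class matrices — eigenvalues 1.8/0.2, major
axis rotated ±25°, traces equal: when class matrices are near-isotropic the
leading-axis orientation is undefined under the permutation null, the null
genome-wide maximum angle saturates at π/2, and the G_max angle scan has no
power for any effect size, which is worth knowing before applying it to
standardized uncorrelated traits); and 100 seeds for the
canalization-reversal and top-hit phenomenology (which needs observed
statistics only). These sizes keep the whole suite a few minutes long while
leaving the pass thresholds (±0.03 around the nominal 5% error rate; ≥80%
or ≥90% detection) several binomial SDs away from their expectations.

## Known limitations

* Only observed markers are tested; there is no interval mapping or
  pseudomarker imputation between markers.
* The covariance scans work on family means, not on an individual-level
  mixed-model G estimate; with ~160 markers × 1000 permutations × 2 classes
  this is what keeps a scan tractable, at the cost of conflating family-mean
  sampling noise into G.
* The Krzanowski scan compares subspaces of fixed dimension k; directions
  carrying little variance dilute the index, making it conservative
  relative to the G_max angle.
* The trace-form Box's M ignores orientation entirely (by design —
  complementarity with the angle methods), and the permutation null, not an
  asymptotic F reference, carries its calibration.
* Multivariate (MANOVA-style) HIF analysis is out of scope; only the
  univariate mixed models are implemented.
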
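# vcqtl

Genome-wide mapping of QTL that control trait **(co)variances** — not just
trait means — in biparental line crosses (recombinant inbred panels), with
the companion analyses for heterogeneous-inbred-family (HIF) epistasis
experiments. The motivating biology is flowering phenology in a
*Boechera stricta*-style RIL panel, where one major locus acts as a
threshold-like signal integrator: depending on the environment, its two
homozygotes differ in *how variable* flowering time is across genomic
backgrounds (genetic canalization, with a direction that can reverse
between environments), which in turn reshapes the multi-trait genetic
covariance matrix (genetic constraint within an environment, GxE across
environments).

## Who this is for

Quantitative geneticists with a line-cross panel — a marker map, a
families × markers genotype table coded as two homozygote classes, and
family-mean phenotypes across traits/environments — who want to scan for:

* **variance QTL** (genetic canalization): per-marker Brown-Forsythe test
  (Levene's test on class-median deviations) on a single trait,
* **covariance-structure QTL**: per-marker comparison of the two
  within-class G matrices by size (trace-form Box's M,
  `M = N·ln S − Σ Vᵢ·ln Sᵢ`), orientation (angle between leading
  eigenvectors G_max, folded into [0, π/2]), or k-dimensional subspace
  overlap (Krzanowski index, the sum of eigenvalues of `AᵀBBᵀA`, scanned
  as its negative),

with family-wise significance from the genome-wide maximum-statistic
permutation null (phenotype rows shuffled whole against the genotype
matrix), plus the `Vm/Vp`–`Vv/Vp` decomposition of a significant locus
(variance explained by the class-mean difference, `pq(μ₁−μ₂)²`, versus the
class-SD difference, `pq(σ₁−σ₂)²`). A threshold/sigmoid flowering-time
simulator generates panels with exactly this structure for testing and
power analysis, and a REML mixed-model module analyses HIF experiments
(genotype × background epistasis F tests, random-effect likelihood-ratio
tests, qPCR ΔCt expression models). See `docs/methods.md` for the models
and all defaults.

## Worked example

```python
import vcqtl as v

# a simulated RIL panel: 178 families, 164 markers on 7 linkage groups,
# threshold-model phenotypes in six environments
gmap  = v.default_map()
focal = v.default_focal_marker(gmap)           # the major 'nFT'-like locus
model = v.default_model(gmap, focal)
geno  = v.simulate_ril_genotypes(v.RILDesign(gmap), seed=1009)
phen  = v.simulate_threshold_phenotypes(geno, model, focal, seed=1010)

# preprocess: standardize traits, drop distorted markers (MAF < 0.33)
phen_s = v.standardize(phen)
geno_f = v.filter_maf(geno)

# variance-QTL scan of flowering time in a mildly flowering-inhibiting
# environment, 1000 genome-wide permutations
scan = v.scan_variance(geno_f, phen_s, "flowering-time@12h18C4w",
                       n_perm=1000, seed=1011)
print(scan.sort_values("statistic", ascending=False).head(1))
#    marker  linkage_group    cM  statistic  perm_p  n_CO  n_MT
# 12   M013              1  66.0      97.85     0.0    86    83

d = v.decompose_at_marker(geno_f, phen_s, "flowering-time@12h18C4w", focal)
print(f"Vm/Vp = {100*d.Vm_over_Vp:.1f}%, Vv/Vp = {100*d.Vv_over_Vp:.1f}%")
# Vm/Vp = 23.3%, Vv/Vp = 18.8%
```

The top marker is the focal locus itself: its Brown-Forsythe statistic
(97.8) exceeds every genome-wide maximum from 1000 permutations
(`perm_p = 0`), and the locus explains 23% of pooled trait variance through
its class-mean difference and a further 19% through its class-variance
difference — a variance-controlling QTL. The same panel scanned with
`v.scan_covariance(..., method="boxm")` on the flowering-time/leaf-number
pair flags the same locus as changing G-matrix size (Box's M ≈ 167,
`perm_p = 0`).

The same operations are scriptable from a shell:

```bash
vcqtl simulate --seed 1 --out sim/
vcqtl scan-var --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
               --trait flowering-time@12h18C4w --n-perm 1000 --seed 2 \
               --out scan.tsv --decompose
vcqtl scan-cov --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
               --traits flowering-time@16h25C4w,leaf-number@16h25C4w \
               --method boxm --n-perm 1000 --seed 3 --out cov.tsv
vcqtl hif-anova --data sim/hif.tsv --response Flowering_time
```

## HIF experiments

`fit_hif_mixed_model(data, response)` fits
`response ~ genotype * HIF + (1|Family) + (1|Block)` by REML and reports
Type III F for the fixed terms (the genotype × HIF interaction is the
epistasis test) with containment denominator df, plus 1-df likelihood-ratio
χ² for the random terms. `fit_expression_model` and
`test_bud_association` do the same for qPCR ΔCt tables
(ΔCt = reference Ct − target Ct, negative in the expected regime, analysed
untransformed). Input formats follow published HIF supplement layouts; see
`vcqtl.dataio.read_hif_table` / `read_expression_table`.

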
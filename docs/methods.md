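# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `invgwas`.

## The mixed model and the score test

Per trait, the null model is `y = Xβ + b + ε` with `b ~ N(0, τ_g K)`,
`ε ~ N(0, τ_e I)`; `X` contains an intercept and the binary *Wolbachia*
indicator, `y` are per-line trait means (Gaussian throughout — line means,
not individual-level counts). REML is exact for a single random effect:
after one eigendecomposition `K = U S Uᵀ`, the restricted likelihood is a
function of the variance ratio `λ = τ_g/τ_e` alone, with β and τ_e profiled
out in closed form. λ is optimized on a log-spaced grid over
`{0} ∪ [1e-6, 1e6]` (49 points) followed by bounded Brent refinement;
boundary estimates (τ_g = 0) are permitted and reported as such. With
`K = I` the variance split is unidentifiable and only `τ_g + τ_e` is
meaningful (it equals the REML residual variance).

Variants are scored without refitting: `T = (gᵀPy)²/(gᵀPg)`, with `P` the
REML projection under the fitted covariance, compared to χ²₁. The score
test also emits the effect approximation `β̃ = gᵀPy/gᵀPg` and
`se² = 1/gᵀPg` for colocalization. Missing dosages are mean-imputed
(per-variant line-drop is available as an option); variants are filtered at
the score stage to MAF ≥ 0.05 and missingness ≤ 0.15 on the included lines.
Permutations shuffle only the trait vector; covariates and the GRM stay
attached to lines, and both the null model and the scores are recomputed
per replicate. Pairwise-complete GCTA relatedness can carry slightly
negative eigenvalues under genotype missingness; eigenvalues above
`-0.1·trace(K)/n` are clipped to zero inside the REML, anything worse is an
error.

A deliberate property of this design, verified empirically: when the tested
variant's LD structure is itself inside the GRM (the Full strategy on a
panel with a strong inversion), score statistics deflate — proximal
contamination. Calibration of the χ²₁ null is therefore checked on panels
whose GRM is built from unlinked variants; on inversion panels the
permutation-exceedance machinery, which is exchangeability-based and
immune to the deflation, carries the inference.

## Relatedness matrices

* **VanRaden (Full)**: `K = ZZᵀ / (2Σ p_j(1-p_j))` with `Z` the
  column-centered dosages; missing dosages mean-imputed to `2p` before
  centering. Recipe filters: MAF > 0.05, missing < 0.20 (strict, as are all
  threshold comparisons in the package).
* **GCTA (LD)**: per-variant standardized products averaged with
  pairwise-complete counts; recipe: MAF > 0.05, missing < 0.15, then greedy
  left-to-right LD pruning (r² ≤ 0.2 retained, pairwise distance ≤ 5 kb is
  "in window", earlier position wins). The two missing-data conventions
  (mean imputation vs pairwise exclusion) mirror the two reference
  estimators and are both tested.
* **LOCO**: the GCTA recipe restricted to arms other than the excluded one;
  one sub-GRM per arm ("2L", "2R", "3L", "3R", "X" in the full scenario).

Monomorphic-after-subsetting variants are dropped with a logged count by
the VanRaden builder and are an error for the GCTA estimator (its
standardization divides by `p(1-p)`); the recipe wrappers filter first.

## Genotype and trait PCA

Genotype PCA standardizes columns as `(g − 2p)/√(2p(1−p))`, zeroes missing
entries after centering (equivalent to mean imputation), and takes the SVD;
scores are left singular vectors scaled by singular values, and each
component's largest-magnitude loading is made positive so permutation
comparisons and plots are reproducible. PC ~ karyotype models use
homozygous lines only, `F = (n−2)R²/(1−R²)` with df (1, n−2), and
karyotype-shuffling permutations; "significant" means the observed R²
strictly exceeds the 95th-order-statistic of (by default) 100 permutations.

Trait matrices are completed by regularized iterative PCA: start at column
means; iterate {standardize columns (sd with n−1), rank-`ncp` SVD with
singular values shrunk as `d ← max((d² − σ̂²)/d, 0)` where σ̂² is the mean
discarded squared singular value, rebuild, restore scale, overwrite only
the originally missing cells} until the RMS change of imputed cells falls
below `tol` (default 1e-6). Observed cells are never modified;
non-convergence returns with a flag and warning. The shrinkage perturbs the
plain rank-`ncp` least-squares objective slightly, so the observed-cell
reconstruction error is non-increasing only up to ~1e-3 relative near the
fixed point — the completion is validated by recovery properties
(exact rank-1 completion; beats column-mean imputation on low-rank + noise
matrices), not by matching any reference tool cell-for-cell, because the
reference's exact σ̂² estimator is not published. `ncp` defaults to 2 (the
analyses use PC1/PC2). Trait PCA itself is correlation-based — unit-variance
scaling is the single biggest fidelity assumption, chosen because trait
compendia mix heterogeneous units. Karyotype contrasts on trait PCs use
Welch's unequal-variance t (the classes are unbalanced; the
Welch–Satterthwaite df is real-valued).

## Inversion–trait models and the matched-frequency null

Inversion effects on traits are OLS fits on karyotype-homozygous lines only
(heterozygous lines carry an unknown within-line inversion frequency and
are excluded; multiple inversions are fitted marginally, never jointly).
The empirical benchmark refits the same model on variants matched to the
inversion's allele frequency — `f = (2·n_INV + n_HET)/(2·n_called)` by
default, homozygote proportion as an option — within ±1% (on the folded
scale), on the same arm, outside the inversion body and > 2 Mb from both
breakpoints. Draws are without replacement when the pool allows, otherwise
with replacement plus a warning; each draw's model uses the lines
homozygous at that variant (dosage 0 or 2). A trait is flagged
inversion-associated when its model has p < 0.05 AND its R² strictly
exceeds the 95% quantile (95th order statistic of 100 draws) of the
matched-null R² distribution. Under pure-noise traits the flag rate is
bounded by the nominal 5% (measured ~2%: the conjunction is conservative).

The ancestry extension fits Ancestry-only, Inversion-only and Full models
against the intercept-only null (F tests) plus nested Full-vs-component
F tests, with trait-shuffling permutations for all five statistics.

## Bin summaries, exceedance, enrichment

Hits are variants with p < 10⁻⁵; the genomic inflation factor is the median
of the χ²₁-quantile-transformed p-values divided by the χ²₁ median
(0.454936…, computed from `scipy.stats.chi2.ppf`, verified against
numerical CDF inversion). Deriving χ² from p rather than carrying the score
statistic makes the summary usable on any p-value source and is identical
for χ²₁ score tests by construction. Variants in the 2 Mb breakpoint-buffer
class count as "outside" for binning (the binning is binary). "Exceeds
permutations" always means strictly greater than the `⌈0.95·n⌉`-th order
statistic of the permutation sample; under exchangeability this fires with
probability 6/101 ≈ 6% at n = 100, which is the interpretive anchor for
the observed false-positive rates. Method and region contrasts are
two-sided Fisher's exact tests on 2×2 exceedance tables, with a
Haldane-corrected (+0.5) auxiliary odds ratio when a margin is zero.
Binomial proportions are reported with Wilson intervals. Enrichment
contrasts the top-k (default 500; ties broken by arm, position) hits
against candidate-outlier flags over the run's own post-filter variant
universe; candidate sets (XtX*/BF-style with POD-calibrated empirical
p-values) are consumed as inputs — the differentiation statistics
themselves are out of scope, and the synthetic module fabricates sets with
controlled enrichment for testing.

## Colocalization

Per SNP, Wakefield's log approximate Bayes factor is
`½log(1−r) + ½rz²`, `r = W/(V+W)`, with `V = se²` from the score test and
prior effect sd `√W = 0.15 × sd(trait)` (quantitative-trait convention; the
trait here is a PC projection). The five-hypothesis posterior
(H0 none / H1 trait-1 only / H2 trait-2 only / H3 two distinct causal
variants / H4 one shared variant) uses prior-weighted log-space sums of
per-SNP (products of) ABFs with priors p1 = p2 = 1e-4, p12 = 1e-5,
assuming at most one causal variant per trait per window; the
implementation is verified against exhaustive enumeration over causal
configurations. Windows are half-open `[start, start+10000)` stepped by
5 kb from the arm's first variant position rounded down to a step multiple;
windows with fewer than 5 scored SNPs are emitted but flagged skipped.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
fly population history — no recombination-map realism, no selection, no
demographic history. Each line draws a karyotype (INV with probability
`q`, HET with a separate fraction that defaults to 0 because the panel is
inbred). The INV haplotype carries the alternate allele at every "tagging"
variant; a line's allele matches its arrangement's haplotype with
probability `1 − leak(d)`, `leak(d) = min(leak₀ + d/ℓ, 0.5)`, `d` the
distance to the nearest breakpoint (0 inside). HET lines draw the two
haplotypes independently and can be dosage-1 inside the inversion; outside
the body a single haplotype is drawn (inbreeding homogenizes). Variants
beyond the leakage zone draw an allele frequency from Beta(a, b) and lines
are homozygous Bernoulli draws. Missingness is MCAR.

Defaults, chosen once as the study conditions: 200 lines (the DGRP has
~205); five arms at *D. melanogaster* lengths with 500 variants each (desk
scale — the real panel has ~2M variants; this is the largest determinant of
how test statistics scale); one In(2L)t-like inversion (2L:2,225,744–
13,154,180) at line frequency q = 0.25; MAF spectrum Beta(0.5, 2.5)
(rare-skewed); missingness 3%; leak₀ = 0.02 and ℓ = 4 Mb so tagging decays
to noise ≈2 Mb past the breakpoints (the real LD-decay profile around
In(2L)t is not quantified anywhere; these are free knobs, not estimates);
African-ancestry fractions Beta(1.5, 6); *Wolbachia* at 50%.

Traits are `y = β_inv·1[INV] + Σβ_j g_j + β_w·wolb + ε` with variance
shares of a unit-variance trait: inversion 0.10 (the reported scale for
inversion-associated line means), polygenic 0.25 over 50 loci drawn off
the inversion arms (so the background is independent of tagging; missing
dosages mean-imputed), *Wolbachia* 0.02, residual the remainder. β_inv is
solved from the empirical karyotype-indicator variance so the expected
share hits the target; loadings alternate in sign across traits by
default. The acceptance machinery verifies the mean realized R² across
200 replicate traits is 0.10 within Monte-Carlo error.

All randomness flows through Philox counter-based generators keyed by
`(master seed, component name, index)` via CRC32-hashed
`SeedSequence` spawn keys, so output is bit-identical across runs and
platforms and adding traits never perturbs genotypes.

What passing tests on this generator do **not** show about real data: no
nested or overlapping inversions, no inversion×inversion or heterozygote
effects (excluded by design), no realistic recombination or selection, a
single global LD-decay law, and variant density ~3 orders of magnitude
below the real panel — so absolute hit counts and maxima of test
statistics are conservative relative to the real study, while directions
of contrasts transfer.

## Problem sizes and known limitations

Tests and the acceptance script run desk-scale configurations chosen as
the package's own experimental design: 120–200 lines, 2–5 arms, 150–3000
variants per arm, 25–100 permutations, 40–200 replicate traits. At the
calibrated 10% trait share and 200 lines, the p < 10⁻⁵ hit threshold sits
close to the power boundary: the probability that a LOCO scan finds
strictly more inside-inversion hits than the Factored-out scan in a single
replicate is ≈0.78 (the Factored-out scan essentially always finds zero,
so the direction itself is unambiguous; the losses are 0–0 ties at
unlucky trait draws). The replicate-level win rate reported by the
acceptance script should be read with that in mind.

The Factored-out inversion list follows the five-inversion formula
(In(2L)t, In(2R)NS, In(3R)P, In(3R)K, In(3R)Mo) and is configurable.
Whether matched variants must additionally lie outside the inversion body
(beyond the 2 Mb breakpoint rule) is ambiguous in the source methods; both
constraints are enforced. The null-model fit for each matched draw uses
that variant's own homozygote subset, not the inversion's. X-chromosome
dosage compensation is not special-cased (inbred lines make it moot).
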
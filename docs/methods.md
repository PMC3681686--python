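# Methods

## Model

For one probe and one SNP across *t* tissues, let n_k individuals contribute
tissue *k* (individuals may overlap arbitrarily between tissues) and
N = Σ n_k.  Expression is standardized per tissue and probe (mean 0, unit
n−1 variance), stacked tissue-major into y ∈ R^N, and modeled as

    y = X a + Z b + u + e,   u ~ N(0, σ²_g K),   e ~ N(0, σ²_e I)

* X (N × t): per-tissue intercept indicators;
* Z (N × t): per-tissue allele dosages (arbitrary real coding; 0/1/2 for a
  biallelic SNP), zero outside the tissue's block;
* K (N × N): 0/1 sharing matrix, K_ij = 1 iff rows i and j come from the
  same individual.  K = M M' for the row-to-individual indicator M, so it is
  PSD with unit diagonal.

The random effect u carries the within-individual, across-tissue
correlation; e is independent noise.  On the standardized scale
σ²_g + σ²_e ≈ 1 and σ²_g is the across-tissue correlation of one
individual's expression.

## Variance components

(σ²_g, σ²_e) are estimated by maximum likelihood (not REML, matching the
association-mode convention of spectral mixed-model solvers).  With
V = σ²_e (δK + I), δ = σ²_g/σ²_e, a one-time eigendecomposition K = UΛU'
turns every likelihood evaluation into O(N·p) work: fixed effects and σ²_e
profile out analytically at each δ.  δ is searched on a 100-point log₁₀ grid
over [1e−5, 1e5] (all points evaluated vectorized), refined by bounded
scalar minimization (xatol 1e−8, ≤100 iterations); the boundary δ = 0 is
always evaluated and wins ties, so σ²_g = 0 is returned exactly when the
data prefer no sharing variance.

By default components are fit once per probe under the intercept-only null
design and reused for every SNP (the SNP's contribution to the residual is
negligible at eQTL effect sizes, and the downstream error correction
re-anchors the marginal scale); `per_snp_components` refits under the full
design, which the parameter-recovery experiment uses to estimate on the
generative scale.

## GLS, error correction, decorrelation

Per-tissue effects are b̂ = (X*'V⁻¹X*)⁻¹X*'V⁻¹y with X* = [X | Z], their
covariance Σ the SNP block of (X*'V⁻¹X*)⁻¹.

Two practical mismatches with single-tissue regression are corrected before
meta-analysis: single-tissue estimates are t-distributed, not normal, and
the joint fit pools the residual variance across tissues while per-tissue
regression fits it per tissue.  The correction quantile-matches each
tissue's single-tissue t statistic to a normal z (z = Φ⁻¹(F_t(t; df)), sign
preserved; t = 0 maps to z = 0) and rescales that tissue's standard error to
|b̂/z|, rebuilding Σ around the new diagonal with the original correlation
matrix.  With df → ∞ the correction is the identity.  It is ON by default
(`--no-df-correction` disables it).

The correlated estimates are then "un-correlated": Λᵢ = 1/(Σ⁻¹1)ᵢ.
Feeding (b̂, Λ) to any independent-inputs meta-analysis reproduces the
optimal correlated fixed-effects statistic 1'Σ⁻¹b̂/√(1'Σ⁻¹1) exactly; for
diagonal Σ, Λ is the ordinary variance vector.  The construction is
undefined when some inverse row sum of Σ is non-positive (possible for
covariances far from the positively-shared-sampling regime, e.g. tiny noisy
designs); the pipeline then falls back to the marginal variances with a
logged warning.  Note the price of un-correlating under strong sharing:
with exchangeable correlation ρ across t tissues, Λ = s²(1+(t−1)ρ), so every
per-tissue z is deflated by √(1+(t−1)ρ) relative to its single-tissue value.
This preserves the FE statistic by construction but weakens the
heterogeneity evidence available to the random-effects test and the
m-values — see "Power behaviour" below.

## Meta-analysis

* **FE**: weights w = 1/Λ, z = Σwb̂/√Σw, two-sided normal p.
* **RE2**: likelihood-ratio statistic of (μ, τ²) free vs (0, 0) under
  b̂ᵢ ~ N(μ, Λᵢ + τ²).  ML by the iterative updates
  w = 1/(Λ+τ²), μ ← Σwb̂/Σw, τ² ← max(0, Σw²((b̂−μ)²−Λ)/Σw²), initialized
  at the DerSimonian–Laird moment estimate, convergence 1e−8, ≤1000
  iterations, with a second start at τ² = 0 and an explicit homogeneous
  profile guard at the boundary.  The default p-value is the boundary
  chi-square mixture ½χ²(1)+½χ²(2) — deterministic, but measurably
  *conservative* at small t (rejection ~0.02–0.03 at nominal 0.05 for t = 4;
  max tail-probability excess ~0.09).  A tabulated Monte-Carlo null
  (`build_re2_null_table`, seeded, vectorized, add-one smoothing) provides a
  calibrated alternative and is what the calibration and power experiments
  use.
* **DL**: moment τ² clamped at 0 (equals FE exactly on homogeneous data),
  re-weighted mean, normal z.
* **Heterogeneity**: Q = Σw(b̂−μ_FE)², p from χ²(t−1);
  I² = max(0, (Q−(t−1))/Q)·100.
* t = 1 reduces everything to the single z-test; heterogeneity fields are
  reported missing.

## m-values

For configuration c ∈ {0,1}^t, the prior is exchangeable,
P(c) = B(n₁+α, n₀+β)/B(α, β) with α = β = 1 (uniform over the effect
proportion).  Tissues with cᵢ = 0 contribute null densities N(b̂ᵢ; 0, Λᵢ);
tissues with cᵢ = 1 share one true effect μ with prior N(0, σ²_p),
integrated analytically (the precision-weighted mean's density under
N(0, 1/W + σ²_p) times an explicit scaling factor).  σ²_p defaults to 0.04
(prior sd 0.2, the conventional moderate-effect prior for quantitative
association; configurable via `--sigma-prior2`).  Exact enumeration over all
2^t configurations (log-space, limit 20 tissues) gives
mᵢ = Σ_{c: cᵢ=1} P(B|c)P(c)/Σ_c P(B|c)P(c).  Calls: m > 0.9 present,
m < 0.1 absent, otherwise ambiguous (strict inequalities).

## Tissue-by-tissue baseline

Per-tissue simple regression y = μ + βx + ε with the exact F-test
(F = t², df (1, n−2)).  A pair is called when min-p < α/t — the plain
Bonferroni division that matches the study-wide false-positive rate of a
meta-analysis run at α.  A perfect fit reports p at the 1e−300 floor.

## Synthetic data and experiments

The generator draws stacked expression from MVN(0, σ²_g K + σ²_e I) —
sampled exactly as per-individual effects plus noise — and adds
effect·dosage in the chosen effect tissues; genotypes are Binomial(2, maf)
dosages.  Study conditions: 100 individuals, 4 tissues, full sharing
(every individual contributes every tissue), maf 0.3.  σ²_g = 0.3,
σ²_e = 0.7 are stand-ins for averaged real-data components (not published
values).  Sharing regimes `none` and fractional presets (e.g. 0.34, 0.11)
emulate disjoint and partially-overlapping cohorts.

What the generator does *not* emulate: probe-level correlation between
genes, non-normal expression noise, linkage between SNPs, population
structure, and batch effects.  Passing tests therefore demonstrate internal
statistical correctness under the stated model, not robustness to every
feature of real expression data.

* **Type-I calibration**: 10,000 null replicates under full sharing;
  rejection at α = 0.05 for the pipeline's FE and RE2 (tabulated null), and
  for a naive arm that feeds per-tissue OLS estimates to FE as if tissues
  were independent.  The naive arm's inflation (~0.16) is the failure mode
  the mixed model exists to prevent.
* **Power**: four scenarios (effect in 1, 2, 3, 4 of 4 tissues) at
  α = 1e−5 for meta methods and α/4 per tissue for TBT, 1,000 replicates.
  Scenario effect sizes 0.8/0.7/0.7/0.5 were calibrated once so the leading
  method lands power ≈ 0.5–0.6 (mid-range), using a single rule across
  scenarios.
* **Split-permute**: one synthetic "tissue" of 108 samples is split into
  three pseudo-tissues of 36; permuting expression within pseudo-tissues
  outside the effect set destroys the genotype link there while preserving
  the marginal distribution.  Gold-standard eQTLs are probes significant on
  the full cohort; detection and per-tissue prediction in the split data use
  the same threshold.  Ten partitions are averaged.  The m-value rule is
  scored correct when all three calls match the truth, ambiguous if any call
  is ambiguous, incorrect otherwise; the p-value rule (p < α/3 ⇒ present)
  has no ambiguous category.

## Power behaviour and known limitations

* Under full sharing with σ²_g = 0.3, the un-correlating deflation
  (√(1+3ρ) ≈ 1.38 per tissue at t = 4) means the random-effects test cannot
  overtake the tissue-by-tissue baseline when only 2 of 4 tissues carry the
  effect: TBT tests each tissue at full marginal strength while every
  meta-analysis input is shrunk.  RE2 still clearly beats FE there, wins
  outright at 3 of 4, and FE wins at 4 of 4; with weaker sharing (smaller
  σ²_g, partial overlap, or the disjoint pseudo-tissues of the split
  experiment) RE2's advantage over TBT reappears.
* The asymptotic mixture p-value for RE2 is conservative at small t; use
  the tabulated null when calibrated tail probabilities matter.
* σ²_g's own sampling noise at 100 individuals (sd ≈ 0.07) bounds how
  tightly recovery experiments can pin it: the median relative error of the
  ML estimate is ≈ 15% at these sizes, an estimator-noise floor rather than
  a bias.
* The FDR option is Benjamini–Hochberg (via statsmodels), a standard
  substitute for q-value estimation.
* Numbers in the results TSV carry 6 significant digits; p-values are
  floored at 1e−300.
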
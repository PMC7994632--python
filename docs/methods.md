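# Methods

`ricemr` estimates the causal effect of rice yield-component traits —
grains per panicle (GPP), kilo-grain (1000-grain) weight (KGW, g) and
tillers per plant (TP) — on yield per plant (YD, g), by chaining
mixed-model GWAS, inverse-variance meta-analysis, two-sample Mendelian
randomization (MR) and superior-allele pyramiding. This note records the
models, the defaults and why, the numerical conventions, and what the
synthetic data generator does and does not emulate.

## Mixed-linear-model association (gwas_lmm)

Per dataset (one population in one environment) and trait, the model is

    y = 1·mu + x_j·beta_j + g + e,   g ~ N(0, A·sigma_g²),  e ~ N(0, I·sigma_e²)

with A the VanRaden genomic relationship matrix Z Zᵀ/m over column-
standardized dosages (missing dosages mean-imputed per SNP). Variance
components are fit once under the null by REML, profiled to a
one-dimensional search over h² = sigma_g²/(sigma_g² + sigma_e²) on [0, 1]
in the GRM eigenbasis (bounded scalar minimization, xatol 1e-6), and held
fixed for every per-SNP generalized-least-squares test — the EMMAX
approximation, which trades a per-SNP REML refit for a single
eigendecomposition and matches the defaults of the standard MLMA tools.
P-values use the two-sided normal reference, consistent with the meta
stage's normal theory. Degenerate cases: an identity-like GRM leaves
sigma_g and sigma_e unidentifiable (the profile likelihood is flat); the
convention is h² = 0 with a warning, under which the scan reduces exactly
to OLS. QC retains SNPs with MAF strictly above the floor (default 0.05)
and missingness strictly below the cap (default 0.20); both inequalities
are strict.

## Meta-analysis (meta_gwas)

The primary combiner is fixed-effect inverse-variance weighting
(w_i = 1/se_i²), with Cochran's Q about the fixed-effect mean,
I² = max(0, (Q − df)/Q), and a switch to a random-effects model when
I² ≥ 50%. The random-effects model is DerSimonian–Laird
(tau² = max(0, (Q − df)/(Σw − Σw²/Σw)), re-weight by 1/(se² + tau²)):
it is in closed form, standard, and fully testable against a brute-force
oracle. Alleles are aligned by A1/A2 matching with beta sign-flip;
strand-ambiguous (A/T, C/G) SNPs pass through with a warning since the
generator never produces strand flips. SNPs observed in a subset of
datasets are combined over that subset. Genome-wide significance is
p < 1e-6, strict.

A practical caveat the tests exposed: with only k = 2 datasets the switch
fires whenever Q ≥ 2 (about 16% of homogeneous SNPs, since Q ~ chi²₁),
and the k = 2 DL estimate is very conservative — a genuinely associated
SNP can lose genome-wide significance purely through a finite-sample
fluctuation of its two betas. This is a property of the prescribed rule,
not a defect of the implementation; the end-to-end recovery test accepts
the small tail it induces.

## Instrument selection (instruments)

A SNP instruments exposure X on outcome YD if it is (i) genome-wide
significant for X in the meta scan (p < 1e-6), (ii) unconfounded — not
directly testable, addressed by construction in simulation — and (iii)
exclusive: p > 0.05 for *every other* component trait's meta statistic.
Survivors are greedily LD-pruned scanning by ascending exposure p
(snp_id breaks ties deterministically); a SNP is kept only if r² ≤ 0.01
with every SNP already kept, so of an LD pair the larger-p member is
discarded. LD is the squared Pearson correlation of dosages; when several
population panels are supplied it is computed after centering dosages
within each panel and pooling (a stratification-adjusted estimator —
allele-frequency differences between populations otherwise masquerade as
linkage and prune valid instruments). `derive_se` reconstructs
se = |beta|/Φ⁻¹(1 − p/2) from printed (beta, p) pairs; it is the exact
inverse of the two-sided normal p and is used only for published-table
inputs, never for internally estimated statistics.

## MR estimators (mr_core)

All estimators consume per-SNP Wald ratios beta_Y/beta_X with first-order
delta-method SEs se_Y/|beta_X| (exposure-side uncertainty ignored — the
standard two-sample construction), so inverse-variance weights are
beta_X²/se_Y².

* **IVW**: weighted mean of ratios; SE = (Σw)^(-1/2) · max(1, √(Q/(k−1)))
  — the multiplicative random-effects convention, so over-dispersed sets
  get wider intervals and homogeneous sets keep the fixed-effect SE
  (floored at 1, and exactly 1 when k = 1). This convention, not plain
  fixed-effect, reproduces the published worked example's intervals.
* **Weighted median** (k ≥ 3): sort ratios, form standardized cumulative
  weights s_j = Σ_{i≤j} w̃_i − w̃_j/2, linearly interpolate the ratio at
  s = 0.5 (clamped to the extreme ratios outside [s_1, s_k]). The source
  analyses print no SE recipe; the SE here is the standard deviation of
  the estimate over a seeded parametric bootstrap (default 10000 draws,
  ratio* ~ N(ratio, se_ratio), weights fixed). The point estimate is the
  deterministic reproduction target; the SE is explicitly stochastic.
* **MR-Egger** (k ≥ 3): orient every instrument to beta_X > 0 (flipping
  beta_Y jointly), then weighted least squares of beta_Y on beta_X with a
  free intercept, weights 1/se_Y²; coefficient SEs from the WLS
  information matrix scaled by max(1, √(RSS_w/(k−2))). The orientation
  convention is what reproduces the published intercepts.
* **Heterogeneity**: Cochran's Q over the ratios about the IVW center.
* **Sign split**: instruments partition by the sign of their Wald ratio
  (zero counts as positive); each subgroup is analyzed independently.
  This is the rule under which the published mixed-sign (KGW) subgroup
  estimates reproduce.

95% CIs are estimate ± 1.959964·SE everywhere; p-values two-sided normal.

Reproduction precision: SEs back-derived from printed p-values inherit
the tables' 3-decimal rounding. This is negligible except where p is
printed very near 1 (0.997, 0.955 in the KGW-positive subgroup), which
limits that subgroup's reproduction to a few percent relative; the other
instrument sets reproduce to the printed precision.

## Superior alleles and pyramiding (pyramiding)

At each significant locus, lines are grouped by genotype *class*
(hom-ref/het/hom-alt — classes, not a dosage slope, because heterozygous
F1 classes can be superior under non-additivity); the class with the
highest mean of the locus's defining trait (its component trait for
indirect loci, yield for direct loci) is the superior genotype, ties
going to the lower dosage class. Lines are scored by the number of loci
at which they carry the superior class; mean yield is reported per count,
groups with fewer than 3 lines are omitted, and retained groups are
compared pairwise by Fisher's LSD on the one-way-ANOVA pooled error
(t = |Δmean|/√(MSE(1/n_a + 1/n_b)), df = N − k). Class means pool all
datasets by default (averaging environments per line).

## Candidate genes (annotation)

Genes within ±200 kb of a SNP (distance 0 inside the gene body, else
distance to the nearer boundary) are candidates, ranked nearest-first —
except that user-supplied curated (cloned, trait-relevant) gene ids rank
ahead of proximity. The ±200 kb reading of "a 200-kb region around" was
chosen over ±100 kb and is configurable.

## Synthetic data (synthetic_data)

The generator emulates the study design the pipeline targets: two (or
more) hybrid-rice populations, each phenotyped in one or more
environments, with LD-structured biallelic SNPs.

* **Genotypes**: two haplotypes per line; along a haplotype each allele
  copies its left neighbour with probability `ld_rho`, else is a fresh
  Bernoulli draw at that SNP's frequency (frequencies uniform in
  `maf_range`). The adjacent-pair r² of this process has a closed form
  used as a test oracle. Default `maf_range` for study simulation is
  (0.1, 0.5) — common variants, so that every planted causal SNP carries
  usable association information regardless of its frequency draw.
* **Component traits** = intercept + Σ beta_j·dosage_j (sparse major
  loci) + polygenic term + environment shift + Gaussian noise. The
  polygenic term is built on a random subset of non-causal SNPs with
  Gaussian effects and rescaled so it contributes a set fraction
  (default 0.35) of genetic variance; the noise SD is then solved so the
  realized genetic fraction equals the requested h². Giving the GRM this
  diffuse signal is what lets the LMM stage estimate a meaningful h².
* **Yield** = intercept + 0.25·GPP + 1.5·KGW + 3.75·TP + direct-effect
  loci + noise. The weights are the linearization of the agronomic
  identity YD = GPP·TP·KGW/1000 around (150 grains, 25 g, 10 tillers),
  with intercept −75 g so mean yield sits near 37 g/plant; they
  reproduce the field's qualitative ordering (TP > KGW > GPP per unit).
  Default major effects are ~0.4 trait-SD per allele (SD targets 30
  grains, 2.5 g, 2.5 tillers), sized so planted instruments reach
  genome-wide significance reliably at the panel sizes the tests use;
  causal loci for different traits are spaced far apart so LD never
  couples two traits' instruments.
* **Environments** of one population share genotypes and differ only by
  additive shifts and fresh noise (no G×E), mirroring the
  per-environment-GWAS-then-meta design without extra unidentified
  structure. Note this makes meta-analysis across environments of the
  same population mildly anti-conservative (their estimates share the
  genotype-sampling noise) — as it is in the real design.
* **Exclusion modes**: `disjoint` (default) guarantees causal sets of
  different component traits do not overlap. `strict` additionally
  projects each component trait orthogonal to the *other* traits'
  causal-SNP dosages within each population, enforcing the MR exclusion
  restriction in-sample. Rationale: with merely disjoint sets, a valid
  instrument's p-value against another trait is uniform, so it fails the
  p > 0.05 exclusivity screen 5% of the time per trait and full recovery
  of a planted instrument set becomes a coin flip; `strict` makes the
  generator's guarantee ("valid instruments exist and are findable")
  actually hold. The projection has rank ≈ 12–16 against n ≥ 600 lines,
  perturbing the trait's own architecture negligibly.

What the generator does **not** emulate: the real crossing scheme
(male-sterile × restorer pedigrees), heterosis/dominance, realistic rice
LD maps and allele-frequency spectra, G×E, selection, and genotyping
error. Passing tests therefore demonstrate correctness of the inference
machinery under a linear additive world, not robustness to those
real-data features.

## Problem sizes used by the test suite

The end-to-end properties run at desk scale, chosen to keep the whole
suite in a few minutes of one CPU while preserving the statistical
behaviour being tested: instrument recovery on 10 seeded studies of
2 populations × 1000 lines × 5000 SNPs (6 instruments per trait,
h² = 0.8, no polygenic background so "exactly recovered" is well
defined); IVW coverage on 50 studies of 2 × 600 lines × 2500 SNPs
(h² = 0.6, polygenic fraction 0.2); null calibration on 2 × 500 lines ×
2000 SNPs; weighted-median robustness at the summary level (8
instruments, 2 invalid carrying < 50% of weight). The published worked
example runs in milliseconds from the bundled tables.

## Known limitations

* The REML search assumes a single GRM; no leave-one-chromosome-out
  variant, so per-SNP tests carry mild proximal contamination.
* No covariates are included by default (the fit accepts an optional
  fixed-covariate matrix).
* The weighted-median SE is bootstrap-based and therefore seed-dependent;
  only the point estimate is deterministic.
* `derive_se` assumes the printed p came from a two-sided normal test of
  the printed beta; p-values printed near 1 make the derived SE
  ill-conditioned.
* With k = 2 studies the I² ≥ 50% random-effects switch is noise-driven
  (see the meta section); four or more datasets behave much better.
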
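# Methods

This note documents the models, defaults and numerical choices behind
`epimr`, and what the synthetic-data generator does and does not establish.

## Two-sample MR

Exposure (CpG methylation) and outcome (complex trait) associations come
from non-overlapping samples.  The Wald ratio β̂ = Γ̂/γ̂ uses the
first-order delta-method SE σ_Y/|γ̂|, which ignores exposure-side
uncertainty: with a weak instrument this is anti-conservative (relative
bias of order 1/F where F ≈ z², the instrument F-statistic).  The IVW
combination is fixed-effect with weights γ̂ⱼ²σ_Yj⁻²; with one instrument it
reduces exactly to the Wald ratio, and with k identical instruments the SE
shrinks by exactly 1/√k.  P-values are two-sided standard normal —
summary-data asymptotics, not t — and significance in the phenome scan uses
a strict inequality against the Bonferroni threshold α/(n_CpG × n_trait),
with the denominator counting instrumented CpGs.  Asymptotic power for a
standardized effect β on an instrument explaining r² of the exposure is
Φ(−z_{1−α/2} + |β|√(n r²)) + Φ(−z_{1−α/2} − |β|√(n r²)).

MR-Egger, weighted-median and heterogeneity statistics are out of scope:
the design targets CpGs instrumented by one or two cis-mQTLs, where those
estimators are undefined or uninformative.

## Instrument selection (conditional-and-joint approximation)

Candidates are cis (strictly within 1 Mb of the CpG) with marginal
P strictly below 1e-7.  Forward stepwise selection refits the joint model
of current picks plus each candidate using the summary-statistic
approximation b = (D^½ R D^½)⁻¹ D β̂, where R is the reference-panel LD
matrix, D = diag(2f(1−f)) the Hardy–Weinberg genotype variances, and the
phenotypic (and residual) variance is fixed at 1 because all traits are
standardized; the joint covariance is (D^½ R D^½)⁻¹/n with n the median
sample size.  A candidate enters when its joint p is smallest, below the
threshold, and its panel r² with every selected variant is below 0.9 (a
collinearity guard mirroring common conditional-analysis defaults).
Singular LD submatrices drop the offending candidate with a warning.
Deterministic tie-breaks (p, then position, then id) make the output
invariant to input row order.

## Harmonization and proxies

Outcome records are aligned to the exposure's effect allele: direct match,
allele swap (beta negated, EAF reflected), or strand complement.
Palindromic variants (A/T, C/G) are dropped when either EAF is missing or
lies in [0.42, 0.58]; otherwise they are oriented by frequency concordance.
Instruments absent from an outcome dataset are replaced by the best panel
proxy within ±500 kb when its r² strictly exceeds 0.8; the allele map
follows the sign of the dosage correlation so the harmonized effect
direction does not depend on which of the two variants is used.

## Multiple-trait colocalization

Per-variant evidence is Wakefield's log approximate Bayes factor
lABF = ½[log(1−r) + z²r], r = W/(V+W), with prior effect-variance
W = 0.04 (SD 0.2 on standardized effects) per trait.  For three traits the
15 configuration classes assign each trait to "unassociated" or to a
causal-variant group; class evidence sums the product of group-summed ABFs
over all assignments of *distinct* variants to groups.  Multi-group sums
use inclusion–exclusion with signed log-sum-exp; a cancellation guard
treats residuals below 1e-12 of the leading term as exact zeros (the
combinatorially impossible classes cancel exactly in real arithmetic).
Priors are per variant: p1 = 1e-4 (one associated trait), p2 = 1e-6 (two
traits sharing a variant), p3 = 1e-7 (all three sharing), multiplied per
group.  PPA_abc is the posterior of the single class in which one variant
drives all three traits; classes like ab.c are reported but do not count
toward the 0.8 decision rule.  The gene scan analyses every gene whose
annotated interval lies within 100 kb of the CpG (distance to the nearest
edge), intersects the three variant grids with the panel, drops panel
MAF < 5%, and requires at least 50 remaining variants.  No multiplicity
correction is applied to PPAs.  Because lABFs depend only on z², the scan
needs no allele harmonization.

## Orientation

Instrument-explained variance from summary data is r² = z²/(z²+n−2),
exactly the squared genotype–phenotype correlation implied by the
regression t-statistic (the simulator tests verify this identity to
1e-10).  The Steiger comparison uses a two-sample Fisher-z test —
appropriate because exposure and outcome r² come from non-overlapping
cohorts — at decision level 0.05; otherwise the direction is
indeterminate.  Reverse MR instruments the complex trait with its
genome-wide-significant variants (p < 5e-8), LD-pruned at panel r² < 0.1
within ±500 kb, and additionally Steiger-filtered: a variant explaining
more variance in methylation than in the trait is primarily an mQTL and
would re-import the forward effect into the reverse estimate, so it is
excluded.  Sign chaining multiplies the EWAS exposure→methylation effect
with the MR methylation→trait effect; the label ("raises"/"lowers") is
produced mechanically from the sign product with no phenotype knowledge.
Cross-sample comparisons report sign concordance and the two-sample
heterogeneity z = (β₁−β₂)/√(se₁²+se₂²).

## Synthetic data

Haplotypes are first-order autoregressive latent Gaussians thresholded at
the MAF quantile (a Gaussian copula), two independent haplotypes per
person.  Thresholding attenuates correlation, so the latent AR parameter
is pre-compensated with the inverse arcsine map (ρ_latent = sin(πρ/2));
the resulting *genotype* correlation decays approximately as
`ld_rho`^distance.  Each cohort — mQTL, eQTL, GWAS, panel — draws
independent genotypes from one population model, honouring the two-sample
assumption.  All phenotypes are standardized, so effects are SD/SD.

Scenarios: `shared` (one variant drives methylation; expression and trait
are downstream via `beta_me`, `beta_mt`), `distinct` (methylation and the
downstream pair are driven by two variants in weak LD, placed at 1/6 and
5/6 of the region so their panel r² stays ≤ 0.3 despite the slow LD
decay), `null` (nothing genetic), `methylation_only` (an mQTL with no
downstream effect), and `trait_causal` (trait genetic, methylation
optionally downstream via `beta_tm` — the reverse-causation regime).
Summary statistics are per-variant simple linear regressions (beta, SE,
two-sided t-test p clipped into (0,1], dosage EAF, n); monomorphic
variants are emitted with missing beta and excluded downstream.

Defaults encode the data regime the pipeline targets: n_mqtl = 1000 (an
ARIES-sized methylation cohort), n_eqtl = 369 (GTEx v7 whole blood),
n_panel = 503 (1000 Genomes European), n_gwas = 10 000 (a deliberately
desk-scale GWAS; biobank scale is unnecessary for the synthetic effects
and would dominate runtime), 60 variants at 2 kb spacing, MAF in
(0.1, 0.5), ld_rho = 0.9, causal_r2 = 0.2 (mQTL variance explained; chain
studies use 0.3, typical of strong cis-mQTLs and needed for Fisher-z
separation at GTEx sample size), beta_me = 0.6, beta_mt = 0.15, EWAS
effect −0.008 (SE 0.002) matching a prenatal-smoking-scale exposure
effect.  `simulate_chain_study` adds 30 independent background trait loci
(0.8% trait variance each, megabases from the CpG) so that reverse-MR
instrument selection has the trait's own polygenic instruments to draw on;
the multi-CpG study generator gives each trait 5 such loci.  A single
master seed drives per-cohort substreams; fixed seed means bit-identical
emissions, and the pipeline writes tables with fixed float formatting so
reruns are byte-identical.

What the generator does **not** emulate: 450K array measurement error,
cell-composition and batch structure, population stratification, sample
overlap between cohorts, allele-frequency drift between panel and cohorts,
multi-causal-variant architectures, or trans-mQTLs.  A green simulation
test therefore establishes internal statistical correctness of the
pipeline under its own assumptions, not robustness to those violations.

## Numerical choices and degenerate inputs

P-values are clipped to [5e-324, 1] so they stay in (0,1] under underflow.
All evidence accumulation is in log space with max-shift summation.
γ̂ = 0 raises an undefined-ratio error; empty candidate sets raise an
uninstrumentable-CpG signal that the pipeline records and skips.  Rejected
summary rows never abort a read; they are counted and logged.  Ties in
top-trait selection break on smaller MR p, then lexicographic trait id.

## Known limitations

The COJO approximation fixes the residual variance at 1 rather than
re-estimating it per step, which slightly overstates joint SEs for large
effects.  The Wald SE ignores exposure-side uncertainty (anti-conservative
for weak instruments).  Colocalization supports at most three traits and
one causal variant per trait per region.  Proxy search assumes the panel
matches the GWAS population.
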
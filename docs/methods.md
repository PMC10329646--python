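# Methods

This note documents the statistical models implemented in `proteopheno`,
the defaults they use, what the synthetic-data generator does and does
not emulate, and the numerical conventions chosen where the field leaves
them open.

## Synthetic study generator

**Genotypes.** Each LD block draws, per haplotype, a standardized AR(1)
Gaussian vector with lag-one correlation ρ (`within_block_rho`, default
0.8); variant *j* carries the alternate allele when its latent value
falls below Φ⁻¹(MAF_j), and a genotype is the sum of two independent
haplotypes. Blocks are mutually independent. The construction gives
tunable within-block LD without a reference panel, preserves
Hardy–Weinberg proportions by design, and makes dosage correlation equal
to the phi coefficient of the thresholded bivariate normal — which is
*attenuated* relative to the latent ρ: at ρ = 0.95 and MAF 0.3 the
genotype r² is ≈ 0.63, and the maximum attainable r² for a thresholded
pair at ρ = 0.95 is ≈ 0.64 even at MAF 0.5. Tests therefore check LD
against the closed-form bivariate-normal oracle rather than against the
latent ρ. Variants are laid out as `chrom:pos:ref:alt` on one chromosome
(default chr12 from 39 Mb in 5 kb steps, so a 500-variant study spans
the 39–41.5 Mb window used by the MR exclude-region configuration).

**Proteins.** The latent level of aptamer *k* is
Σ β·dosage + covariate effects + N(0, noise_sd²), with β in SD-protein
per alternate allele and noise_sd = 1. Covariates are age ~ U(40, 90),
sex ~ Bernoulli(0.5), and a categorical plate/array label per cohort
(two plates per cohort by default). Aptamers map to genes placed on a
distant chromosome (trans) unless a planted effect is tagged cis, in
which case the gene span is placed at the variant (±10 kb), making the
variant a cis-pQTL under the ±1 Mb rule.

**Raw export.** RFU-like raw measurements are
`10^(3 + 0.2·latent)`: an affine log10 placement (values around 10³,
0.2 decades per latent SD — the dispersion scale of aptamer RFU data).
The QC module's log10 + z-score step inverts this exactly, recovering
the standardized latent level. A pure `10^latent` export was rejected:
with latent SD 1 it produces a lognormal with a ten-fold spread whose
upper tail the 1.5×IQR rule masks at ~14% per aptamer, dragging call
rates below the 85% stage and destroying planted signals — a property of
the export scale, not of real aptamer data. Plate scale factors and
cross-plate CVs are emitted at nominal values (1.0 and 0.05) unless an
`ArtifactPlan` overrides them; missingness is injected at planned rates.

**Disease.** Liability = Σ_k θ_k · (genetic component of protein k) +
direct SNP effects + N(0, 1); cases are the top `prevalence` quantile
(default 0.2). Because mediation acts through the genetic component, the
two-sample MR estimand on the liability-linear GWAS scale equals the
planted θ (up to the exposure-side rescaling noted under MR below). The
GWAS sample (default n = 20 000) is drawn fresh from the same variant
definitions, giving a genuine two-sample design. Both a liability-linear
and a logistic (log-OR) export are available; the linear export is the
default because it keeps the MR estimand in closed form.

**What the generator does not emulate:** realistic human LD maps,
imputation uncertainty, population structure and relatedness,
X-chromosome dosage, batch drift over time, or assay nonlinearity.
Passing recovery tests therefore demonstrate the correctness of the
inference machinery under the stated model, not robustness to those
real-data complications.

## QC cascade

Stages run in a fixed order: scale factor → CV → IQR → call rate →
normalize. All thresholds are strict inequalities (a value exactly at a
boundary is retained). Conventions chosen where common practice varies:

- *Scale factor*: an aptamer is removed if on **any** plate
  |scale − plate median| > 0.5 (an aggregate mode is available).
- *IQR rule*: quartiles by linear interpolation (numpy's default);
  values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are **set missing**, not
  winsorized; aptamers with < 4 observed values are skipped.
- *Call rate*: stage 1 removes samples and aptamers below 65% on the
  incoming table; rates are recomputed before the 85% stage, which
  handles aptamers before samples (order configurable).
- *Normalization*: per aptamer, x → (log10 x − mean)/sd over observed
  values with the **sample** sd (n−1); log10([10, 100, 1000]) = [1, 2, 3]
  has sample sd exactly 1, so the z-scores are [−1, 0, 1]. Constant
  columns are dropped with a warning (sd below 1e-12, the rounding floor
  of a constant column); nonpositive values raise, naming the cell.

Every removal is recorded once, with its stage and reason, and the
report asserts aptamers_in = aptamers_out + removed.

## pQTL scan and meta-analysis

Per (variant, aptamer): OLS of the normalized level on alternate-allele
dosage plus covariates — age, sex, array indicators (treatment coded)
and genotype principal components (default 10, computed from the
mean-imputed standardized dosage matrix; the synthetic population has no
structure, but the covariate is kept to mirror the intended adjustment
set). The implementation residualizes via Frisch–Waugh–Lovell and is
exactly equal to full-design least squares; p-values use the t
distribution with the residual degrees of freedom. Missing dosages or
levels are handled per-pair complete-case; zero-variance variants yield
NA records with a flag.

Meta-analysis is fixed-effect inverse-variance: β_meta = Σw_iβ_i/Σw_i
with w_i = 1/se_i², se_meta = (Σw_i)^(−1/2), Q = Σw_i(β_i − β_meta)²,
I² = max(0, (Q − (k−1))/Q)·100. Alleles are harmonized to the first
reporting cohort's effect allele (sign and frequency flipped on swaps).
The forest report gives each pair's sign concordance with the meta
direction and flags I² > 50. Note that under a true common effect
Q ~ χ²(k−1), so with six cohorts the I² > 50 flag fires in ≈ 7.5% of
pairs by chance; the tests assert that rate, not zero.

## Conditional–joint selection

The joint model over a SNP set S is reconstructed from marginal summary
statistics: with per-allele betas b_j, their ses, the per-variant dosage
sds and the LD correlation matrix R, the correlation-scale effects are
r_j = b_j·sd_j/sd_y (sd_y recovered from the single-SNP identity
sd_y² = sd_j²(b_j² + se_j²(n−2))), and the joint solution is
β_std = R_S⁻¹ r_S with residual variance (1 − β_stdᵀr_S)(n−1)/(n−|S|−1).
When R comes from the same sample as the marginal statistics this equals
individual-level multiple regression **exactly**, which the tests assert
to 1e-6. Stepwise selection enters the free SNP with the smallest
conditional p below `p_entry` (default 5×10⁻⁸, the genome-wide
convention; ties broken by smallest p then lexicographic ID), refits the
joint model, and drops any selected SNP whose joint p rises above the
threshold; SNPs with r² ≥ 0.9 to the selected set are excluded as
collinear. Conditioning a SNP on itself returns 0 with a `self` flag;
singular LD submatrices raise, naming the variants.

LD pruning is greedy keep-best-p with a strict r² > 0.85 drop rule (a
pair at exactly 0.85 is kept, with a 1e-12 tolerance for float rounding
of the boundary). The discovery loop runs: PheWAS of the sentinel
(BH across all aptamers, q ≤ 0.05) → stepwise selection per significant
aptamer → prune the SNP union by best p → PheWAS of the surviving SNPs →
aptamer union; two rounds by default.

## PWAS

Weight models per aptamer, trained on covariate-residualized levels over
the cis window (±1 Mb of the gene) plus conditionally selected trans
SNPs: *top1* (single best SNP, weight = its marginal beta) and *elastic
net* (α chosen once by inner CV at l1_ratio 0.5); the model with the
higher out-of-fold R² (5-fold) is retained. A model is usable only if
its out-of-fold R² is positive **and** the prediction–observation
correlation is nominally significant (p < 0.05) — without the
significance screen, ~20% of pure-noise proteins pass on R² alone.

The association statistic is z = wᵀz_gwas / √(wᵀRw), with GWAS z-scores
harmonized to the weights' alt-allele orientation and R eigenvalue-floored
at 1e-8. It is exactly the instrument's GWAS z for a top1 model, scale
invariant in w, and standard normal under a null GWAS (asserted by a
1000-replicate calibration). Post-processing merges significant features
(BH, q ≤ 0.05) whose weight-SNP spans come within 100 kb into loci;
within a locus, features are taken strongest-|z| first and each next
feature's z is conditioned on the accepted ones through the correlation
of their genetically predicted levels; a feature whose predicted level
is fully explained by accepted features (conditional variance < 1e-6) is
conditionally dependent by definition.

## Mendelian randomization

Instruments: exposure p < 5×10⁻⁸, present in the outcome table, alleles
harmonized (outcome beta flipped on A1/A2 swap; palindromic SNPs dropped
when the allele frequency is in [0.42, 0.58]; other mismatches dropped),
clumped at r² ≤ 0.001 keeping the smallest exposure p, and F =
(β_exp/se_exp)² ≥ 10. Estimation: Wald ratio θ = β_out/β_exp with
first-order se = se_out/|β_exp| for one instrument; fixed-effect IVW
(weighted regression through the origin, weights 1/se_out²) for two or
more. Fixed-effect rather than multiplicative-random-effects IVW is
deliberate given the small instrument counts this design produces (≤ 4);
with many heterogeneous instruments the fixed-effect se would be
anti-conservative. The three sensitivity configurations are: all
instruments; excluding a pleiotropic region (default chr12:39–41.5 Mb);
cis-only (within 1 Mb of the gene's coding span). One scale note: the
exposure betas are on the *normalized* protein scale, so the estimand is
θ·sd(latent protein) — e.g. a planted θ = 0.3 on a protein whose genetic
component contributes variance 0.14 corresponds to 0.32 per normalized
SD. The first-order Wald se ignores exposure-side sampling error (the
no-measurement-error approximation), which is standard at F ≫ 10.

## Differential levels and cell-type enrichment

Group contrasts are OLS of each aptamer on a group indicator plus
covariates (age, sex, array by default; sex contrasts adjust for age and
array only, and refuse sex among the covariates), with BH within the
contrast. Without covariates the contrast reduces exactly to the
equal-variance two-sample t-test. Groups with < 2 samples skip the
contrast with a warning.

Cell-type specificity: a gene is specific to the cell type carrying
strictly more than 50% of its summed expression (with a 1e-9 tolerance
so that an exact half — up to the rounding of the share normalization —
is *not* specific). Enrichment of a target set against the background is
FC = (specific fraction in target)/(specific fraction in background)
with a hypergeometric upper-tail p (the probability of at least the
observed count in a draw of the target's size); Fisher's one-sided exact
test on the same table is offered as an alias and is numerically
identical. The test is the standard choice for set enrichment; a
permutation null is out of scope.

## Pipeline defaults and problem sizes

The bundled demo study is three cohorts of 700/700/600 samples, 500
variants in twenty 25-SNP blocks (ρ = 0.8, MAF 0.1–0.5) spanning
chr12:39–41.5 Mb, 60 aptamers, a sentinel cis-pQTL affecting three
aptamers (β 0.45–0.55), an LD-independent trans SNP affecting three
(one shared), one mediating protein at θ = 0.3, prevalence 0.2, and a
20 000-sample GWAS. These sizes give each planted signal a noncentrality
well beyond the 5×10⁻⁸ entry threshold (the weakest signal's expected
|t| ≈ 13) while the whole chain completes in about a minute on one CPU;
recovery-rate tests use the same power reasoning (weakest signal ≥ 97%
power per replicate at the MAF floor) so that failure indicates an
implementation defect rather than sampling noise. Determinism: one root
seed spawns named substreams (variants, genotypes per cohort,
covariates, proteins, GWAS), so any stage is byte-reproducible given the
seed.

## Known limitations

- The LD model cannot produce genotype r² above the thresholded-Gaussian
  bound for a given latent ρ; designs needing near-perfect proxies must
  raise ρ toward 1.
- COJO-style conditional statistics assume the LD reference matches the
  association sample; reference-mismatch corrections are not
  implemented (in-sample LD is used throughout).
- The per-SNP GWAS ignores covariates (the simulated liability has
  none) and the logistic export refits per variant, which is slow for
  large variant counts.
- MR sensitivity estimates use the same instrument list across
  configurations rather than re-clumping within each subset.
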
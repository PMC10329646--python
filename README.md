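# proteopheno

Proteogenomic inference for aptamer-based proteomics: from raw
measurement QC through trans-pQTL discovery to causal-protein nomination.

The package is built for studies that ask *which proteins does a disease
risk locus regulate, and which of those proteins are causal for the
disease*. It chains the standard analysis stages behind one importable
API:

1. **Aptamer QC & normalization** — plate scale-factor and cross-plate CV
   filters, 1.5×IQR outlier masking, a two-stage (65% / 85%) call-rate
   cascade, and per-aptamer log10 + z-score normalization.
2. **pQTL scanning** — covariate-adjusted linear association of every
   variant with every aptamer (age, sex, genotype PCs, array batch), per
   cohort and pooled.
3. **Meta-analysis** — fixed-effect inverse-variance weighting across
   cohorts with Cochran's Q and I² heterogeneity and forest-style
   sign-concordance reporting.
4. **PheWAS + conditional selection** — Benjamini–Hochberg FDR across
   aptamers for a sentinel SNP, then stepwise conditional–joint SNP
   selection from summary statistics (marginal betas + an LD reference),
   LD pruning at r² > 0.85, and an iterated discovery loop that turns one
   sentinel into the locus's full SNP × protein architecture.
5. **PWAS** — per-aptamer SNP weight models (top1 and elastic net,
   chosen by cross-validated R²) over cis+trans SNP sets and the weighted
   association statistic z = wᵀz_gwas / √(wᵀRw) against disease GWAS
   z-scores, with 100 kb locus merging and conditional post-processing.
6. **Mendelian randomization** — two-sample MR with instrument screening
   (p < 5×10⁻⁸, clumping, F ≥ 10, allele harmonization), Wald ratio /
   fixed-effect IVW estimation, and three sensitivity configurations:
   all instruments, excluding a pleiotropic region, cis-only.
7. **Differential levels & cell-type enrichment** — covariate-adjusted
   group contrasts (case / prodromal / mutation carriers, sex strata) and
   the >50%-of-total-expression cell-type specificity rule with
   hypergeometric set enrichment.

Because real cohort genotype/proteome data of this kind is
access-controlled, the package ships a first-class **synthetic study
generator**: LD-blocked genotypes (latent-Gaussian AR(1) haplotypes),
planted cis/trans aptamer effects, plate artifacts, covariates, and a
liability-threshold disease partially mediated by protein levels — plus a
truth ledger so every stage can be scored against what was planted.

## Worked example

Each script in `examples/` exercises one capability. The MR example
plants a protein that mediates disease liability at θ = 0.3 and asks
whether two-sample MR recovers it:

```bash
$ python examples/06_mendelian_randomization.py
instruments selected: ['12:39025000:T:C'] (F = [185.0])
planted causal effect theta = 0.3 liability units per SD-protein
  all            : wald, theta = 0.336 [0.292, 0.381], p = 6.80e-49
  exclude_region : no instruments
  cis_only       : wald, theta = 0.336 [0.292, 0.381], p = 6.80e-49
```

The instrument is strong (F = 185), the 95% interval covers the planted
θ, and because the single cis instrument lies inside the excluded region
the exclude-region configuration is empty — the pattern that separates
region-driven signals from region-independent ones.

The full chain runs from one command:

```bash
proteopheno demo --seed 1 --outdir demo_out
```

which simulates a three-cohort study (2000 samples, 500 variants in LD
blocks spanning chr12:39–41.5 Mb, 60 aptamers) with a sentinel cis-pQTL,
one LD-independent trans signal, five affected aptamers and one
disease-mediating protein, then prints

```
sentinel: 12:39310000:G:A
discovered variants: ['12:39310000:G:A', '12:40435000:T:C']
discovered aptamers: ['APT0001', 'APT0002', 'APT0003', 'APT0004', 'APT0005']
```

— exactly the planted architecture — and writes per-stage TSVs (QC
report, association and meta tables, PWAS and MR results, enrichment)
plus a manifest with the seed, config hash and file hashes.
`proteopheno run --config examples/pipeline.yaml --outdir out` does the
same from a YAML study description.

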
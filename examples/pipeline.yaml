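# Full-pipeline configuration for `proteopheno run --config examples/pipeline.yaml`.
# The simulation block defines the synthetic study; everything else sets
# analysis thresholds.  Planted variant IDs follow the chrom:pos:ref:alt
# layout produced by the generator (pos_start + 5000 * index on chr12).
simulation:
  n_samples: {cohortA: 500, cohortB: 500}
  n_variants: 100
  block_sizes: [10, 10, 10, 10, 10, 10, 10, 10, 10, 10]
  within_block_rho: 0.7
  maf_range: [0.2, 0.45]
  n_aptamers: 12
  seed: 5
  planted_effects:
    - {variant_index: 15, aptamer_id: APT0001, beta: 0.5, cis: true}
    - {variant_index: 15, aptamer_id: APT0002, beta: 0.45}
    - {variant_index: 65, aptamer_id: APT0002, beta: 0.45}
    - {variant_index: 65, aptamer_id: APT0003, beta: 0.5}
  disease:
    protein_mediation: [[APT0001, 0.3]]
    prevalence: 0.2
    n_gwas: 10000
sentinel: auto   # resolved to the first planted variant when "auto"
fdr_level: 0.05
p_entry: 5.0e-8
r2_prune: 0.85
n_pcs: 4
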
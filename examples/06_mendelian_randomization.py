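"""Two-sample MR of a protein on disease with sensitivity configurations.

The protein mediates disease liability at theta = 0.3.  Instruments come
from its pQTL summary statistics; the three configurations (all
instruments / excluding a pleiotropic region / cis-only) probe whether
the estimate survives pleiotropy-robust restrictions.
"""

import dataclasses

from proteopheno import (
    DiseaseConfig,
    PlantedEffect,
    SimulationConfig,
    simulate_disease_gwas,
    simulate_genotypes,
    simulate_proteins,
)
from proteopheno.cojo import LdMatrix
from proteopheno.mr import select_instruments, sensitivity_configs
from proteopheno.pipeline import _assoc_to_gwas_dialect
from proteopheno.scan import linear_scan
from proteopheno.simulate import _variant_table

THETA = 0.3

config = SimulationConfig(
    n_samples={"a": 2000},
    n_variants=30,
    block_sizes=[10] * 3,
    within_block_rho=0.5,
    maf_range=(0.2, 0.4),
    n_aptamers=1,
    seed=41,
)
vid = _variant_table(config).index[5]
config = dataclasses.replace(
    config,
    planted_effects=[PlantedEffect(vid, "APT0001", 0.5, cis=True)],
    disease=DiseaseConfig(protein_mediation=(("APT0001", THETA),), n_gwas=20000),
)
genotypes = simulate_genotypes(config)
proteins, truth, _ = simulate_proteins(genotypes, config)
gwas = simulate_disease_gwas(config, truth)
assoc = linear_scan(genotypes, proteins, None, n_pcs=0)
exposure = _assoc_to_gwas_dialect(assoc.dropna(subset=["p"]), genotypes.variants)
instruments = select_instruments(exposure, gwas, LdMatrix.from_genotypes(genotypes))

pos = int(genotypes.variants.loc[vid, "pos"])
configs = sensitivity_configs(
    "APT0001",
    instruments,
    exclude_region=("12", 39e6, 39.1e6),  # pleiotropic region containing the cis instrument
    gene_region=("12", pos - 10_000, pos + 10_000),
)
print(f"instruments selected: {list(instruments['SNP'])} (F = {instruments['F'].round(0).tolist()})")
print(f"planted causal effect theta = {THETA} liability units per SD-protein")
for name, r in configs.items():
    if r.method == "none":
        print(f"  {name:15s}: no instruments")
    else:
        lo, hi = r.ci95
        print(f"  {name:15s}: {r.method}, theta = {r.theta:.3f} [{lo:.3f}, {hi:.3f}], p = {r.p:.2e}")
print("-> the 95% interval covers theta; with the single cis instrument inside the")
print("   excluded region, the exclude-region configuration is empty — the pattern")
print("   that separates region-driven signals from region-independent ones")
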
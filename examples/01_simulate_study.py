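"""Build a small synthetic multi-cohort proteogenomic study.

Generates LD-blocked genotypes for two cohorts, plants one cis-pQTL, and
shows that the planted effect is visible in a simple regression.
"""

import dataclasses

import numpy as np

from proteopheno import PlantedEffect, SimulationConfig, simulate_genotypes, simulate_proteins
from proteopheno.simulate import _variant_table

config = SimulationConfig(
    n_samples={"cohortA": 800, "cohortB": 600},
    n_variants=100,
    block_sizes=[20] * 5,
    within_block_rho=0.8,
    maf_range=(0.1, 0.4),
    n_aptamers=10,
    seed=11,
)
variant = _variant_table(config).index[30]
config = dataclasses.replace(
    config, planted_effects=[PlantedEffect(variant, "APT0001", 0.4, cis=True)]
)

genotypes = simulate_genotypes(config)
proteins, truth, covariates = simulate_proteins(genotypes, config)

freq = genotypes.allele_freq()[variant]
ld = genotypes.dosages.iloc[:, 30:32].corr().iloc[0, 1]
x = genotypes.dosages[variant]
y = proteins.values["APT0001"]
beta = np.polyfit(x, y, 1)[0]

print(f"samples: {len(genotypes.dosages)}, variants: {len(genotypes.variant_ids)}")
print(f"planted cis-pQTL {variant} -> APT0001, beta = 0.4 SD/allele")
print(f"alt-allele frequency at the planted SNP: {freq:.3f}")
print(f"r with the adjacent variant (same LD block): {ld:.2f}")
print(f"naive per-allele regression slope: {beta:.3f}")
print("-> the slope recovers the planted effect; the LD block provides proxies")
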
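"""Protein weight training and the PWAS association statistic.

Trains top1 and elastic-net weight models for a genetically regulated
protein and tests whether its predicted level associates with a disease
GWAS in which the protein mediates risk.
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
from proteopheno.pwas import pwas_assoc, train_weights
from proteopheno.simulate import _variant_table

config = SimulationConfig(
    n_samples={"a": 1500},
    n_variants=40,
    block_sizes=[10] * 4,
    within_block_rho=0.6,
    maf_range=(0.2, 0.4),
    n_aptamers=2,
    seed=31,
)
vid = _variant_table(config).index[15]
config = dataclasses.replace(
    config,
    planted_effects=[PlantedEffect(vid, "APT0001", 0.5, cis=True)],
    disease=DiseaseConfig(protein_mediation=(("APT0001", 0.3),), n_gwas=20000),
)
genotypes = simulate_genotypes(config)
proteins, truth, _ = simulate_proteins(genotypes, config)
gwas = simulate_disease_gwas(config, truth)
ld = LdMatrix.from_genotypes(genotypes)

model = train_weights(genotypes.dosages, proteins.values["APT0001"], seed=1)
model.aptamer_id = "APT0001"
res = pwas_assoc(model, gwas, ld)

print(f"weight model: {model.model}, cv R^2 = {model.cv_r2:.3f} (p = {model.cv_r2_p:.1e})")
print(f"nonzero weights: {len(model.nonzero())}; top SNP {model.nonzero().abs().idxmax()}")
print(f"planted causal SNP: {vid}")
print(f"z_pwas = {res.z:.2f} (p = {res.p:.2e})")
print("-> the genetically predicted protein level associates with disease,")
print("   as expected when the protein mediates part of the liability")
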
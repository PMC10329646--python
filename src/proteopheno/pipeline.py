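"""End-to-end orchestration of the synthetic proteogenomic study.

One call runs the whole inference chain on generated data: simulate ->
QC -> per-cohort and pooled pQTL scans -> fixed-effect meta-analysis ->
sentinel PheWAS / conditional-selection discovery loop -> PWAS -> MR with
sensitivity configurations -> differential protein levels -> cell-type
enrichment, and writes per-stage TSVs plus a manifest with the seed,
config hash and file hashes so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import celltype as ct
from . import cojo, diff, io, mr, pwas, qc, scan
from .simulate import (
    ArtifactPlan,
    DiseaseConfig,
    PlantedEffect,
    SimulationConfig,
    _variant_table,
    export_raw,
    simulate_celltype_expression,
    simulate_disease_gwas,
    simulate_genotypes,
    simulate_proteins,
)

logger = logging.getLogger(__name__)

CELL_TYPES = ["microglia", "astrocyte", "neuron", "oligodendrocyte", "endothelial"]


@dataclass
class RunConfig:
    """Thresholds and study design for one pipeline run."""

    simulation: SimulationConfig
    sentinel: str
    fdr_level: float = 0.05
    p_entry: float = 5e-8
    r2_prune: float = 0.85
    cis_window: float = 1e6
    exclude_region: tuple[str, float, float] = ("12", 39e6, 41.5e6)
    mr_p_max: float = 5e-8
    mr_f_min: float = 10.0
    n_pcs: int = 10
    gwas_scale: str = "liability"
    prodromal_fraction: float = 0.1
    stages: tuple[str, ...] = (
        "simulate",
        "qc",
        "scan",
        "meta",
        "loop",
        "pwas",
        "mr",
        "diff",
        "celltype",
    )

    def __post_init__(self) -> None:
        for name, val, lo, hi in [
            ("fdr_level", self.fdr_level, 0, 1),
            ("p_entry", self.p_entry, 0, 1),
            ("r2_prune", self.r2_prune, 0, 1),
            ("mr_p_max", self.mr_p_max, 0, 1),
        ]:
            if not (lo < val <= hi):
                raise ValueError(f"{name}={val} outside ({lo}, {hi}]")

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), default=str, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def design_demo_study(
    seed: int = 0,
    n_samples: dict[str, int] | None = None,
    n_variants: int = 500,
    block_size: int = 25,
    n_aptamers: int = 60,
    beta: float = 0.5,
    theta: float = 0.3,
    n_gwas: int = 20000,
) -> RunConfig:
    """The bundled demo design: a sentinel cis-pQTL plus one independent
    trans signal, five affected aptamers, one protein mediating disease.

    The sentinel (block 3) raises aptamers 1-3 and is cis to aptamer 1's
    gene; a second, LD-independent SNP (block 12) raises aptamers 3-5.
    Aptamer 1 mediates disease liability at the given theta.  Defaults:
    2000 samples over three cohorts, 500 variants in 25-SNP LD blocks
    spanning chr12:39.0-41.5 Mb, 60 aptamers.
    """
    n_samples = n_samples or {"cohortA": 700, "cohortB": 700, "cohortC": 600}
    base = SimulationConfig(
        n_samples=n_samples,
        n_variants=n_variants,
        block_sizes=[block_size] * (n_variants // block_size),
        within_block_rho=0.8,
        maf_range=(0.1, 0.5),
        n_aptamers=n_aptamers,
        seed=seed,
    )
    variants = _variant_table(base)
    n_blocks = n_variants // block_size
    sentinel_block = min(n_blocks - 1, n_blocks // 10)
    snp2_block = min(n_blocks - 1, (11 * n_blocks) // 20)
    if snp2_block == sentinel_block:
        raise ValueError("demo design needs at least two LD blocks")
    sentinel = variants.index[sentinel_block * block_size + block_size // 2]
    snp2 = variants.index[snp2_block * block_size + block_size // 2]
    effects = [
        PlantedEffect(sentinel, "APT0001", beta * 1.1, cis=True),
        PlantedEffect(sentinel, "APT0002", beta),
        PlantedEffect(sentinel, "APT0003", beta * 0.9),
        PlantedEffect(snp2, "APT0003", beta * 0.9),
        PlantedEffect(snp2, "APT0004", beta),
        PlantedEffect(snp2, "APT0005", beta * 1.1),
    ]
    sim = dataclasses.replace(
        base,
        planted_effects=effects,
        covariate_effects={"APT0006": {"sex": 0.4}, "APT0007": {"age": 0.01}},
        disease=DiseaseConfig(
            protein_mediation=(("APT0001", theta),),
            prevalence=0.2,
            n_gwas=n_gwas,
        ),
    )
    return RunConfig(simulation=sim, sentinel=sentinel)


def _assoc_to_gwas_dialect(assoc: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Reshape one aptamer's association records into the GWAS summary TSV
    dialect (A1 = effect allele = alt)."""
    v = variants.loc[assoc["variant_id"]]
    return pd.DataFrame(
        {
            "SNP": assoc["variant_id"].to_numpy(),
            "CHR": v["chrom"].to_numpy(),
            "POS": v["pos"].to_numpy(),
            "A1": v["alt"].to_numpy(),
            "A2": v["ref"].to_numpy(),
            "FREQ": assoc["effect_allele_freq"].to_numpy(),
            "BETA": assoc["beta"].to_numpy(),
            "SE": assoc["se"].to_numpy(),
            "P": assoc["p"].to_numpy(),
            "N": assoc["n"].to_numpy(),
        }
    )


def _diagnosis_labels(
    genotypes, ledger, config: RunConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Liability-threshold diagnosis for the proteomics samples: cases above
    the prevalence cut, a prodromal band below it, controls elsewhere."""
    from .simulate import genetic_component

    liability = pd.Series(rng.standard_normal(len(genotypes.dosages)), index=genotypes.dosages.index)
    for _, row in ledger.mediation.iterrows():
        liability += row["theta"] * genetic_component(genotypes, ledger, row["aptamer_id"])
    prev = config.simulation.disease.prevalence
    hi = liability.quantile(1 - prev)
    mid = liability.quantile(1 - prev - config.prodromal_fraction)
    label = pd.Series("control", index=liability.index, dtype=object)
    label[liability > hi] = "case"
    label[(liability > mid) & (liability <= hi)] = "prodromal"
    return pd.DataFrame({"diagnosis": label, "liability": liability})


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every enabled stage and return a dict of in-memory results.

    When ``outdir`` is given, each stage writes its TSV/JSON and a
    manifest (seed, config hash, per-file sha256) is emitted at the end.
    """
    res: dict = {"config": config}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def _write(name: str, fn) -> None:
        if out is None:
            return
        path = out / name
        fn(path)
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    stages = set(config.stages)
    sim = config.simulation

    # --- simulate -----------------------------------------------------------
    if "simulate" not in stages:
        raise ValueError("pipeline currently requires the 'simulate' stage")
    genotypes = simulate_genotypes(sim)
    proteins_latent, ledger, covariates = simulate_proteins(genotypes, sim)
    raw = export_raw(proteins_latent, covariates, ArtifactPlan(), seed=sim.seed)
    gwas = simulate_disease_gwas(sim, ledger, scale=config.gwas_scale)
    res.update(
        genotypes=genotypes, ledger=ledger, covariates=covariates, gwas=gwas, raw=raw
    )
    _write("genotypes.dosage.tsv", lambda p: io.write_dosage_tsv(genotypes, p))
    _write("covariates.tsv", lambda p: io.write_covariate_tsv(covariates, p))
    _write("gwas.tsv", lambda p: io.write_gwas_tsv(gwas, p))
    _write("truth.json", lambda p: ledger.to_json(p))

    # --- qc -----------------------------------------------------------------
    if "qc" in stages:
        proteins, qc_report = qc.run_qc(raw, annotations=proteins_latent.annotations)
        res["proteins"] = proteins
        res["qc_report"] = qc_report
        _write("proteins.normalized.tsv", lambda p: io.write_protein_tsv(proteins, p))
        _write(
            "qc_report.json",
            lambda p: p.write_text(json.dumps(qc_report.to_dict(), indent=1)),
        )
    else:
        res["proteins"] = proteins_latent

    proteins = res["proteins"]
    ld = cojo.LdMatrix.from_genotypes(genotypes)
    res["ld"] = ld

    # --- scan (pooled + per-cohort) ----------------------------------------
    if "scan" in stages:
        pooled = scan.linear_scan(genotypes, proteins, covariates, n_pcs=config.n_pcs)
        res["assoc_pooled"] = pooled
        _write("assoc_pooled.tsv", lambda p: pooled.to_csv(p, sep="\t", index=False))
        cohort_assoc = {}
        for cohort in genotypes.samples["cohort"].unique():
            sub = genotypes.subset_cohort(cohort)
            cohort_assoc[cohort] = scan.linear_scan(
                sub, proteins, covariates.loc[covariates.index.intersection(sub.dosages.index)],
                n_pcs=config.n_pcs,
            )
        res["assoc_by_cohort"] = cohort_assoc

    # --- meta ---------------------------------------------------------------
    if "meta" in stages:
        if "assoc_by_cohort" not in res:
            raise RuntimeError("meta stage requires the scan stage output")
        meta = scan.meta_fixed(res["assoc_by_cohort"])
        res["meta"] = meta
        res["forest"] = scan.forest_consistency(res["assoc_by_cohort"], meta)
        _write("meta.tsv", lambda p: meta.to_csv(p, sep="\t", index=False))

    # --- discovery loop -----------------------------------------------------
    if "loop" in stages:
        if "assoc_pooled" not in res:
            raise RuntimeError("loop stage requires the scan stage output")
        loop = cojo.discovery_loop(
            config.sentinel,
            res["assoc_pooled"],
            ld,
            fdr_level=config.fdr_level,
            p_entry=config.p_entry,
            r2_prune=config.r2_prune,
        )
        res["loop"] = loop
        _write(
            "discovery.json",
            lambda p: p.write_text(
                json.dumps({"variants": loop["variants"], "aptamers": loop["aptamers"]}, indent=1)
            ),
        )

    # --- pwas ---------------------------------------------------------------
    if "pwas" in stages:
        if "loop" not in res:
            raise RuntimeError("pwas stage requires the discovery loop output")
        pcs = scan.compute_pcs(genotypes, config.n_pcs)
        design = scan.build_covariate_design(covariates.loc[proteins.values.index], pcs.loc[proteins.values.index])
        X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
        models: dict[str, pwas.WeightModel] = {}
        results: list[pwas.PwasResult] = []
        for apt in res["loop"]["aptamers"]:
            y = proteins.values[apt].dropna()
            Xy = X[proteins.values.index.get_indexer(y.index)]
            coef, *_ = np.linalg.lstsq(Xy, y.to_numpy(), rcond=None)
            resid = pd.Series(y.to_numpy() - Xy @ coef, index=y.index, name=apt)
            ann = proteins.annotations.loc[apt]
            vmeta = genotypes.variants
            cis_mask = (vmeta["chrom"].astype(str) == str(ann.get("gene_chrom"))) & (
                vmeta["pos"].between(
                    float(ann.get("gene_start", np.inf)) - config.cis_window,
                    float(ann.get("gene_end", -np.inf)) + config.cis_window,
                )
            )
            snp_set = list(vmeta.index[cis_mask])
            trans = [v for v in res["loop"]["variants"] if v not in snp_set]
            tags = {v: "cis" for v in snp_set}
            tags.update({v: "trans" for v in trans})
            snp_set = snp_set + trans
            if not snp_set:
                continue
            model = pwas.train_weights(
                genotypes.dosages, resid, snp_set, snp_tags=tags, seed=sim.seed
            )
            model.aptamer_id = apt
            models[apt] = model
            results.append(pwas.pwas_assoc(model, gwas, ld))
        positions = genotypes.variants["pos"].astype(float)
        pwas_table = pwas.postprocess_loci(results, models, positions, ld, fdr_level=config.fdr_level)
        res["pwas_models"] = models
        res["pwas"] = pwas_table
        _write("pwas.tsv", lambda p: pwas_table.to_csv(p, sep="\t", index=False))

    # --- mr -----------------------------------------------------------------
    if "mr" in stages:
        if "loop" not in res:
            raise RuntimeError("mr stage requires the discovery loop output")
        mr_rows = []
        mr_results: dict[str, dict[str, mr.MrResult]] = {}
        for apt in res["loop"]["aptamers"]:
            marg = res["assoc_pooled"][res["assoc_pooled"]["aptamer_id"] == apt]
            exposure = _assoc_to_gwas_dialect(marg.dropna(subset=["p"]), genotypes.variants)
            inst = mr.select_instruments(
                exposure, gwas, ld, p_max=config.mr_p_max, f_min=config.mr_f_min
            )
            ann = proteins.annotations.loc[apt]
            gene_region = None
            if pd.notna(ann.get("gene_chrom", np.nan)):
                gene_region = (
                    str(ann["gene_chrom"]),
                    float(ann["gene_start"]),
                    float(ann["gene_end"]),
                )
            configs = mr.sensitivity_configs(
                apt,
                inst,
                exclude_region=config.exclude_region,
                gene_region=gene_region,
                cis_window=config.cis_window,
            )
            mr_results[apt] = configs
            for name, r in configs.items():
                mr_rows.append(
                    (apt, name, r.method, r.n_snp, r.theta, r.se, r.p)
                )
        mr_table = pd.DataFrame(
            mr_rows, columns=["aptamer_id", "configuration", "method", "n_snp", "theta", "se", "p"]
        )
        res["mr"] = mr_results
        res["mr_table"] = mr_table
        _write("mr.tsv", lambda p: mr_table.to_csv(p, sep="\t", index=False))

    # --- differential levels ------------------------------------------------
    if "diff" in stages:
        rng = np.random.default_rng(np.random.SeedSequence(sim.seed).spawn(7)[-1])
        pheno = _diagnosis_labels(genotypes, ledger, config, rng)
        pheno = pheno.join(covariates[["age", "sex", "array"]])
        adj = scan.build_covariate_design(pheno, include=("age", "sex", "array"))
        contrasts = []
        for comp in ("case", "prodromal"):
            contrasts.append(
                diff.group_compare(
                    proteins.values, pheno, ("control", comp), covariates=adj
                )
            )
        strata = {
            "all": pheno.index,
            "case": pheno.index[pheno["diagnosis"] == "case"],
            "control": pheno.index[pheno["diagnosis"] == "control"],
        }
        adj_nosex = scan.build_covariate_design(pheno, include=("age", "array"))
        sexdiff = diff.sex_difference(proteins.values, pheno, strata, covariates=adj_nosex)
        diff_table = pd.concat(contrasts + [sexdiff], ignore_index=True)
        res["phenotypes"] = pheno
        res["differential"] = diff_table
        _write("differential.tsv", lambda p: diff_table.to_csv(p, sep="\t", index=False))

    # --- cell-type enrichment ----------------------------------------------
    if "celltype" in stages:
        ann = proteins.annotations
        genes = list(ann["gene"]) if "gene" in ann else [f"GENE{i:04d}" for i in range(1, sim.n_aptamers + 1)]
        gene_of = dict(zip(ann.index, genes))
        truth_genes = {gene_of[a] for a in ledger.affected_aptamers() if a in gene_of}
        plan: dict[str, object] = {g: "microglia" for g in truth_genes}
        rng = np.random.default_rng(np.random.SeedSequence(sim.seed).spawn(9)[-1])
        for g in genes:
            if g not in plan:
                plan[g] = "neuron" if rng.random() < 0.1 else None
        expr = simulate_celltype_expression(genes, CELL_TYPES, plan, seed=sim.seed)
        calls = ct.assign_specificity(expr)
        target = sorted(
            {gene_of[a] for a in res.get("loop", {}).get("aptamers", ledger.affected_aptamers()) if a in gene_of}
        )
        enr = {
            cell: ct.enrichment(target, genes, calls, cell) for cell in CELL_TYPES
        }
        res["celltype_calls"] = calls
        res["celltype_enrichment"] = enr
        _write(
            "celltype_enrichment.tsv",
            lambda p: pd.DataFrame(
                [dataclasses.asdict(e) for e in enr.values()]
            ).to_csv(p, sep="\t", index=False),
        )

    if out is not None:
        manifest = {
            "seed": sim.seed,
            "config_hash": config.config_hash(),
            "stages": sorted(stages),
            "files": written,
            "versions": _versions(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return res


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("numpy", "scipy", "pandas", "statsmodels", "scikit-learn", "proteopheno"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
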
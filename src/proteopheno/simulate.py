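"""Synthetic multi-cohort proteogenomic study generator.

Builds the fixtures a CSF proteogenomics analysis consumes — LD-blocked
biallelic genotypes, aptamer-level protein measurements with planted
cis/trans SNP effects and plate artifacts, covariate tables, a
liability-threshold disease GWAS partially mediated by protein levels, and
a brain cell-type expression table — together with a :class:`TruthLedger`
recording every planted effect so that downstream recovery tests can score
themselves against the ground truth.

The LD model is a latent-Gaussian AR(1) per block: each haplotype draws a
standardized AR(1) Gaussian vector with lag-one correlation ``rho`` and
carries the minor allele wherever the latent value falls below the MAF
quantile; a genotype is the sum of two independent haplotypes.  This gives
tunable within-block r^2 without a reference panel, and exact independence
across blocks.

The disease is a liability-threshold model: liability is the sum of the
*genetic* component of each mediating protein scaled by its causal effect
theta (liability units per SD-protein), any direct SNP effects, and unit
Gaussian noise; cases are the samples above the (1 - prevalence) quantile.
Because mediation acts through the genetic component, the two-sample MR
estimand on the liability-linear GWAS scale equals the planted theta.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlantedEffect",
    "DiseaseConfig",
    "SimulationConfig",
    "GenotypeMatrix",
    "ProteinMatrix",
    "TruthLedger",
    "simulate_genotypes",
    "simulate_proteins",
    "simulate_disease_gwas",
    "simulate_celltype_expression",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PlantedEffect:
    """One planted SNP -> aptamer effect.

    beta is in SD-protein per copy of the effect (alternate) allele.  When
    ``cis`` is true the aptamer's coding gene is placed at the variant's
    position so the effect is a cis-pQTL; otherwise the gene lives on
    another chromosome and the effect is trans.
    """

    variant_id: str
    aptamer_id: str
    beta: float
    cis: bool = False


@dataclass(frozen=True)
class DiseaseConfig:
    """Liability-threshold disease partially mediated by protein levels."""

    protein_mediation: tuple[tuple[str, float], ...] = ()
    direct_snp_effects: tuple[tuple[str, float], ...] = ()
    prevalence: float = 0.2
    n_gwas: int = 20000


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic multi-cohort run.

    n_samples maps cohort name -> sample count.  block_sizes must sum to
    n_variants; variants within a block share an AR(1) latent correlation
    ``within_block_rho`` and blocks are mutually independent.  Variant IDs
    are "chrom:pos:ref:alt" with positions laid out from ``pos_start`` in
    steps of ``pos_step`` on ``chrom``.
    """

    n_samples: Mapping[str, int]
    n_variants: int
    block_sizes: Sequence[int]
    within_block_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_aptamers: int = 20
    planted_effects: Sequence[PlantedEffect] = ()
    covariate_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 1.0
    disease: DiseaseConfig = field(default_factory=DiseaseConfig)
    seed: int = 0
    chrom: str = "12"
    pos_start: int = 39_000_000
    pos_step: int = 5_000
    age_range: tuple[float, float] = (40.0, 90.0)
    plates_per_cohort: int = 2

    def __post_init__(self) -> None:
        if sum(self.block_sizes) != self.n_variants:
            raise ValueError(
                f"block_sizes sum to {sum(self.block_sizes)}, expected {self.n_variants}"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must be in [0, 1)")
        if not (0.0 < self.disease.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")

    # deterministic sub-streams: one root SeedSequence, children spawned in a
    # fixed order so every product is byte-identical for a given seed
    def _seeds(self) -> dict[str, np.random.SeedSequence]:
        root = np.random.SeedSequence(self.seed)
        names = ["variants", "genotypes", "covariates", "proteins", "gwas"]
        return dict(zip(names, root.spawn(len(names))))


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage table plus variant and sample metadata.

    dosages: DataFrame indexed by sample ID, one column per variant ID,
    values in {0, 1, 2} (float; NaN = missing).
    variants: DataFrame with variant_id, chrom, pos, ref, alt, maf, block.
    samples: DataFrame with sample_id index and a 'cohort' column.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame
    samples: pd.DataFrame

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def subset_cohort(self, cohort: str) -> "GenotypeMatrix":
        keep = self.samples.index[self.samples["cohort"] == cohort]
        return GenotypeMatrix(self.dosages.loc[keep], self.variants, self.samples.loc[keep])

    def allele_freq(self) -> pd.Series:
        """Empirical alternate-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def ld(self) -> pd.DataFrame:
        """In-sample genotype correlation matrix (r, not r^2)."""
        return self.dosages.corr()


@dataclass
class ProteinMatrix:
    """Samples x aptamers table with an aptamer -> gene -> region map.

    values are on the analysis scale (SD units after normalization, or the
    simulator's latent scale before raw export).  annotations carry
    aptamer_id (index), gene, gene_chrom, gene_start, gene_end.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def aptamer_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TruthLedger:
    """Planted ground truth for recovery tests.

    effects: one row per planted (variant, aptamer) effect, retrievable by
    that key; mediation: causal protein -> disease theta per aptamer;
    cohort_of: cohort assignment per sample.
    """

    effects: pd.DataFrame
    mediation: pd.DataFrame
    cohort_of: pd.Series

    def lookup(self, variant_id: str, aptamer_id: str) -> float | None:
        m = self.effects[
            (self.effects["variant_id"] == variant_id)
            & (self.effects["aptamer_id"] == aptamer_id)
        ]
        if m.empty:
            return None
        if len(m) > 1:
            raise ValueError(f"duplicate planted effect for ({variant_id}, {aptamer_id})")
        return float(m["beta"].iloc[0])

    def affected_aptamers(self) -> list[str]:
        return sorted(self.effects["aptamer_id"].unique())

    def to_json(self, path) -> None:
        payload = {
            "effects": self.effects.to_dict(orient="records"),
            "mediation": self.mediation.to_dict(orient="records"),
            "cohort_of": self.cohort_of.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            effects=pd.DataFrame(
                payload["effects"], columns=["variant_id", "aptamer_id", "beta", "cis"]
            ),
            mediation=pd.DataFrame(payload["mediation"], columns=["aptamer_id", "theta"]),
            cohort_of=pd.Series(payload["cohort_of"], name="cohort"),
        )


# ---------------------------------------------------------------------------
# genotypes


def _variant_table(config: SimulationConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config._seeds()["variants"])
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_variants)
    refs = rng.choice(list("ACGT"), size=config.n_variants)
    # alt differs from ref by construction
    alts = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
    )
    pos = config.pos_start + config.pos_step * np.arange(config.n_variants)
    blocks = np.repeat(np.arange(len(config.block_sizes)), config.block_sizes)
    ids = [
        f"{config.chrom}:{p}:{r}:{a}" for p, r, a in zip(pos, refs, alts)
    ]
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": config.chrom,
            "pos": pos,
            "ref": refs,
            "alt": alts,
            "maf": mafs,
            "block": blocks,
        }
    ).set_index("variant_id", drop=False)


def _haplotypes(
    rng: np.random.Generator, n_hap: int, block_sizes: Sequence[int], rho: float, mafs: np.ndarray
) -> np.ndarray:
    """Draw n_hap haplotypes under the latent AR(1) threshold model."""
    m = int(np.sum(block_sizes))
    z = np.empty((n_hap, m))
    start = 0
    innov_sd = np.sqrt(1.0 - rho**2)
    for size in block_sizes:
        block = np.empty((n_hap, size))
        block[:, 0] = rng.standard_normal(n_hap)
        for j in range(1, size):
            block[:, j] = rho * block[:, j - 1] + innov_sd * rng.standard_normal(n_hap)
        z[:, start : start + size] = block
        start += size
    thresholds = stats.norm.ppf(mafs)
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate LD-blocked biallelic dosages for every cohort.

    All cohorts share the variant definitions (positions, alleles, MAFs and
    block structure) but draw independent samples, emulating independent
    recruitment from one population.
    """
    variants = _variant_table(config)
    geno_seed = config._seeds()["genotypes"]
    cohort_seeds = geno_seed.spawn(len(config.n_samples))
    frames = []
    sample_rows = []
    for (cohort, n), seed in zip(config.n_samples.items(), cohort_seeds):
        rng = np.random.default_rng(seed)
        h1 = _haplotypes(rng, n, config.block_sizes, config.within_block_rho, variants["maf"].to_numpy())
        h2 = _haplotypes(rng, n, config.block_sizes, config.within_block_rho, variants["maf"].to_numpy())
        dos = (h1 + h2).astype(float)
        ids = [f"{cohort}_S{i:05d}" for i in range(n)]
        frames.append(pd.DataFrame(dos, index=ids, columns=variants.index))
        sample_rows.extend((s, cohort) for s in ids)
    dosages = pd.concat(frames, axis=0)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "cohort"]).set_index("sample_id")
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# proteins and covariates


def _aptamer_annotations(config: SimulationConfig, variants: pd.DataFrame) -> pd.DataFrame:
    """Aptamer -> gene map.  Genes default to a distant chromosome (trans);
    aptamers carrying a cis planted effect get their gene placed at the
    variant's position."""
    ids = [f"APT{i:04d}" for i in range(1, config.n_aptamers + 1)]
    ann = pd.DataFrame(
        {
            "aptamer_id": ids,
            "gene": [f"GENE{i:04d}" for i in range(1, config.n_aptamers + 1)],
            "gene_chrom": "1",
            "gene_start": 10_000_000 + 2_000_000 * np.arange(config.n_aptamers),
        }
    )
    ann["gene_end"] = ann["gene_start"] + 20_000
    ann = ann.set_index("aptamer_id", drop=False)
    for eff in config.planted_effects:
        if eff.cis:
            if eff.variant_id not in variants.index:
                raise KeyError(f"unknown variant {eff.variant_id!r} in planted effect")
            pos = int(variants.loc[eff.variant_id, "pos"])
            ann.loc[eff.aptamer_id, ["gene_chrom", "gene_start", "gene_end"]] = [
                variants.loc[eff.variant_id, "chrom"],
                max(0, pos - 10_000),
                pos + 10_000,
            ]
    return ann


def simulate_covariates(config: SimulationConfig, samples: pd.DataFrame) -> pd.DataFrame:
    """Age (uniform over ``age_range``), sex (Bernoulli 0.5) and a
    categorical plate/array label per cohort."""
    rng = np.random.default_rng(config._seeds()["covariates"])
    n = len(samples)
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n)
    plate = np.empty(n, dtype=object)
    for cohort in samples["cohort"].unique():
        mask = (samples["cohort"] == cohort).to_numpy()
        plate[mask] = [
            f"{cohort}_P{p + 1}"
            for p in rng.integers(0, config.plates_per_cohort, size=int(mask.sum()))
        ]
    return pd.DataFrame(
        {"age": age, "sex": sex, "array": plate, "cohort": samples["cohort"].to_numpy()},
        index=samples.index,
    )


def simulate_proteins(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    covariates: pd.DataFrame | None = None,
) -> tuple[ProteinMatrix, TruthLedger, pd.DataFrame]:
    """Latent protein levels: planted genetic effects + covariate effects +
    Gaussian noise.

    Returns the protein matrix on the *latent* (SD-like) scale, the truth
    ledger, and the covariate table used.  Raw RFU-like export for the QC
    module is ``10 ** latent`` (see :func:`export_raw`), so the QC module's
    log10 + z-score step inverts it.
    """
    if covariates is None:
        covariates = simulate_covariates(config, genotypes.samples)
    ann = _aptamer_annotations(config, genotypes.variants)
    rng = np.random.default_rng(config._seeds()["proteins"])
    n = len(genotypes.dosages)
    y = rng.normal(0.0, config.noise_sd, size=(n, config.n_aptamers))
    y = pd.DataFrame(y, index=genotypes.dosages.index, columns=ann.index)
    for eff in config.planted_effects:
        if eff.aptamer_id not in y.columns:
            raise KeyError(f"unknown aptamer {eff.aptamer_id!r} in planted effect")
        if eff.variant_id not in genotypes.dosages.columns:
            raise KeyError(f"unknown variant {eff.variant_id!r} in planted effect")
        y[eff.aptamer_id] += eff.beta * genotypes.dosages[eff.variant_id]
    # covariate effects: per-aptamer dict with keys among age/sex/array
    age_c = covariates["age"] - covariates["age"].mean()
    for apt, effs in config.covariate_effects.items():
        if apt not in y.columns:
            raise KeyError(f"unknown aptamer {apt!r} in covariate_effects")
        y[apt] += effs.get("age", 0.0) * age_c
        y[apt] += effs.get("sex", 0.0) * covariates["sex"].astype(float)
        arr_eff = effs.get("array", 0.0)
        if arr_eff:
            # alternating plate shift: odd-numbered plates shifted by arr_eff
            odd = covariates["array"].str.endswith("2").astype(float)
            y[apt] += arr_eff * odd
    ledger = TruthLedger(
        effects=pd.DataFrame(
            [dataclasses.asdict(e) for e in config.planted_effects],
            columns=["variant_id", "aptamer_id", "beta", "cis"],
        ),
        mediation=pd.DataFrame(
            list(config.disease.protein_mediation), columns=["aptamer_id", "theta"]
        ),
        cohort_of=genotypes.samples["cohort"].copy(),
    )
    return ProteinMatrix(values=y, annotations=ann), ledger, covariates


@dataclass
class ArtifactPlan:
    """Measurement artifacts to inject into the raw export.

    scale_factor_shifts: (plate, aptamer) -> scale factor recorded for that
    plate (default 1.0 elsewhere).  cv_overrides: (plate, aptamer) -> CV
    recorded for that plate (default baseline_cv).  missing_rate: aptamer ->
    fraction of samples set missing at random.
    """

    scale_factor_shifts: Mapping[tuple[str, str], float] = field(default_factory=dict)
    cv_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    missing_rate: Mapping[str, float] = field(default_factory=dict)
    baseline_cv: float = 0.05


def export_raw(
    proteins: ProteinMatrix,
    covariates: pd.DataFrame,
    artifacts: ArtifactPlan | None = None,
    seed: int = 0,
    log10_loc: float = 3.0,
    log10_scale: float = 0.2,
):
    """Export latent protein levels as RFU-like raw measurements.

    Values are ``10 ** (log10_loc + log10_scale * latent)`` — an affine
    log10 placement (default: measurements around 10^3 with a 0.2-decade
    spread per latent SD, the dispersion scale of aptamer RFU data) that
    the QC module's log10 + z-score step inverts exactly.  Plate metadata
    (scale factors and cross-plate CVs) is generated at nominal values and
    overridden per the artifact plan; missingness is injected at the
    planned rates.  Returns a :class:`proteopheno.qc.RawAptamerData`.
    """
    from .qc import RawAptamerData  # deferred: avoid import cycle

    artifacts = artifacts or ArtifactPlan()
    rng = np.random.default_rng(seed)
    values = np.power(10.0, log10_loc + log10_scale * proteins.values.astype(float))
    plate_of = covariates["array"].astype(str)
    plates = sorted(plate_of.unique())
    apts = proteins.aptamer_ids
    scale = pd.DataFrame(1.0, index=plates, columns=apts)
    cvs = pd.DataFrame(artifacts.baseline_cv, index=plates, columns=apts)
    for (plate, apt), v in artifacts.scale_factor_shifts.items():
        scale.loc[plate, apt] = v
    for (plate, apt), v in artifacts.cv_overrides.items():
        cvs.loc[plate, apt] = v
    values = values.copy()
    for apt, rate in artifacts.missing_rate.items():
        mask = rng.random(len(values)) < rate
        values.loc[mask, apt] = np.nan
    return RawAptamerData(values=values, plate_of=plate_of, scale_factors=scale, cvs=cvs)


# ---------------------------------------------------------------------------
# disease GWAS


def genetic_component(
    genotypes: GenotypeMatrix, ledger: TruthLedger, aptamer_id: str
) -> pd.Series:
    """Sum of planted SNP effects for one aptamer (no noise, no covariates)."""
    out = pd.Series(0.0, index=genotypes.dosages.index)
    rows = ledger.effects[ledger.effects["aptamer_id"] == aptamer_id]
    for _, r in rows.iterrows():
        out += r["beta"] * genotypes.dosages[r["variant_id"]]
    return out


def simulate_disease_gwas(
    config: SimulationConfig,
    ledger: TruthLedger,
    scale: str = "liability",
) -> pd.DataFrame:
    """Simulate an independent disease GWAS sample and its summary table.

    A fresh genotype sample of ``config.disease.n_gwas`` individuals is
    drawn from the same variant definitions (two-sample design).  Liability
    = sum over mediating aptamers of theta * genetic protein component +
    direct SNP effects + N(0,1); cases are above the (1 - prevalence)
    quantile.  ``scale`` selects the reported effect scale: "liability"
    (linear regression of liability on dosage) or "logistic" (log-OR from
    logistic regression of case status).

    Returns a GWAS summary table with columns SNP, CHR, POS, A1, A2, FREQ,
    BETA, SE, P, N (A1 = alternate = effect allele).
    """
    if scale not in ("liability", "logistic"):
        raise ValueError(f"unknown GWAS scale {scale!r}")
    variants = _variant_table(config)
    rng = np.random.default_rng(config._seeds()["gwas"])
    n = config.disease.n_gwas
    h1 = _haplotypes(rng, n, config.block_sizes, config.within_block_rho, variants["maf"].to_numpy())
    h2 = _haplotypes(rng, n, config.block_sizes, config.within_block_rho, variants["maf"].to_numpy())
    dos = (h1 + h2).astype(float)
    dosages = pd.DataFrame(dos, columns=variants.index)

    liability = rng.standard_normal(n)
    for apt, theta in config.disease.protein_mediation:
        rows = ledger.effects[ledger.effects["aptamer_id"] == apt]
        if rows.empty:
            raise KeyError(f"mediating aptamer {apt!r} has no planted genetic effect")
        for _, r in rows.iterrows():
            liability += theta * r["beta"] * dosages[r["variant_id"]].to_numpy()
    for vid, beta in config.disease.direct_snp_effects:
        liability += beta * dosages[vid].to_numpy()
    cutoff = np.quantile(liability, 1.0 - config.disease.prevalence)
    case = (liability > cutoff).astype(int)
    if case.sum() == 0 or case.sum() == n:
        raise ValueError("degenerate disease simulation: zero cases or zero controls")

    X = dosages.to_numpy()
    freq = X.mean(axis=0) / 2.0
    if scale == "liability":
        y = liability
        yc = y - y.mean()
        xc = X - X.mean(axis=0)
        sxx = (xc**2).sum(axis=0)
        beta = (xc * yc[:, None]).sum(axis=0) / sxx
        resid_var = ((yc[:, None] - xc * beta) ** 2).sum(axis=0) / (n - 2)
        se = np.sqrt(resid_var / sxx)
    else:
        import statsmodels.api as sm

        beta = np.empty(X.shape[1])
        se = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            model = sm.Logit(case, sm.add_constant(X[:, j])).fit(disp=0)
            beta[j] = model.params[1]
            se[j] = model.bse[1]
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "SNP": variants["variant_id"].to_numpy(),
            "CHR": variants["chrom"].to_numpy(),
            "POS": variants["pos"].to_numpy(),
            "A1": variants["alt"].to_numpy(),
            "A2": variants["ref"].to_numpy(),
            "FREQ": freq,
            "BETA": beta,
            "SE": se,
            "P": np.clip(p, np.finfo(float).tiny, 1.0),
            "N": n,
        }
    )


# ---------------------------------------------------------------------------
# cell-type expression


def simulate_celltype_expression(
    genes: Sequence[str],
    cell_types: Sequence[str],
    specificity_plan: Mapping[str, object],
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x cell-type nonnegative expression with planned specificity.

    specificity_plan maps gene -> one of: a cell-type name (dominant share
    drawn uniformly in (0.55, 0.9)), None (all shares kept at or below 0.5),
    or an explicit share vector (sequence summing to 1, one entry per cell
    type, in ``cell_types`` order).
    """
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    if k < 2:
        raise ValueError("need at least 2 cell types")
    rows = []
    for g in genes:
        plan = specificity_plan.get(g, None)
        if isinstance(plan, (list, tuple, np.ndarray)):
            shares = np.asarray(plan, dtype=float)
            if shares.shape != (k,) or not np.isclose(shares.sum(), 1.0, atol=1e-9):
                raise ValueError(f"explicit shares for gene {g!r} must sum to 1 over {k} cell types")
        elif plan is None:
            while True:
                shares = rng.dirichlet(np.ones(k) * 2.0)
                if shares.max() <= 0.5:
                    break
        else:
            if plan not in cell_types:
                raise ValueError(f"unknown cell type {plan!r} for gene {g!r}")
            dom = rng.uniform(0.55, 0.9)
            rest = rng.dirichlet(np.ones(k - 1)) * (1.0 - dom)
            shares = np.empty(k)
            idx = list(cell_types).index(plan)
            shares[idx] = dom
            shares[[i for i in range(k) if i != idx]] = rest
        total = rng.lognormal(mean=3.0, sigma=1.0)
        rows.append(shares * total)
    return pd.DataFrame(rows, index=list(genes), columns=list(cell_types))
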
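"""Two-sample Mendelian randomization of protein levels on disease risk.

Instruments are genome-wide significant, mutually independent pQTL SNPs
present in both the exposure (pQTL) and outcome (disease GWAS) summary
tables, harmonized to a common effect allele and screened at the
conventional weak-instrument bound F >= 10.  Estimation is the Wald ratio
for a single instrument and fixed-effect inverse-variance weighting (a
weighted regression of outcome betas on exposure betas through the
origin) for two or more.  Three sensitivity configurations mirror a
pleiotropy-robustness workflow: all instruments, instruments outside a
named pleiotropic region, and cis-only instruments (within 1 Mb of the
protein's coding gene).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cojo import LdMatrix, ld_prune

__all__ = [
    "MrResult",
    "select_instruments",
    "wald_ratio",
    "ivw",
    "sensitivity_configs",
]

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

INSTRUMENT_COLUMNS = [
    "SNP",
    "CHR",
    "POS",
    "effect_allele",
    "other_allele",
    "beta_exposure",
    "se_exposure",
    "p_exposure",
    "beta_outcome",
    "se_outcome",
    "F",
]


@dataclass
class MrResult:
    aptamer_id: str
    method: str  # "wald" | "ivw" | "none"
    n_snp: int
    theta: float
    se: float
    p: float
    configuration: str = "all"

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.theta - 1.96 * self.se, self.theta + 1.96 * self.se)


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LdMatrix | None = None,
    p_max: float = 5e-8,
    f_min: float = 10.0,
    clump_r2: float = 0.001,
    ambiguous_freq: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Select and harmonize MR instruments from two summary tables.

    Both tables use the GWAS dialect (SNP, CHR, POS, A1, A2, FREQ, BETA,
    SE, P, N; A1 = effect allele).  Steps: exposure p < ``p_max``; present
    in the outcome; allele harmonization (outcome beta flipped when A1/A2
    are swapped; unresolvable pairs and palindromic SNPs with frequency in
    the ambiguous band dropped); LD clumping at r^2 <= ``clump_r2`` keeping
    the smallest exposure p; instrument strength F >= ``f_min``.
    """
    exp = exposure[exposure["P"] < p_max].copy()
    if exp.empty:
        return pd.DataFrame(columns=INSTRUMENT_COLUMNS)
    out = outcome.set_index("SNP")
    rows = []
    for _, e in exp.iterrows():
        snp = e["SNP"]
        if snp not in out.index:
            continue
        o = out.loc[snp]
        pal = (str(e["A1"]).upper(), str(e["A2"]).upper()) in PALINDROMIC
        if pal:
            f = float(e.get("FREQ", np.nan))
            if not np.isfinite(f) or ambiguous_freq[0] <= f <= ambiguous_freq[1]:
                continue  # strand-ambiguous, frequency uninformative
        if o["A1"] == e["A1"] and o["A2"] == e["A2"]:
            b_out, se_out = float(o["BETA"]), float(o["SE"])
        elif o["A1"] == e["A2"] and o["A2"] == e["A1"]:
            b_out, se_out = -float(o["BETA"]), float(o["SE"])
        else:
            continue  # allele mismatch, unresolvable
        F = (float(e["BETA"]) / float(e["SE"])) ** 2
        if F < f_min:
            continue
        rows.append(
            (
                snp,
                e["CHR"],
                int(e["POS"]),
                e["A1"],
                e["A2"],
                float(e["BETA"]),
                float(e["SE"]),
                float(e["P"]),
                b_out,
                se_out,
                F,
            )
        )
    inst = pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)
    if inst.empty or ld is None or len(inst) == 1:
        return inst
    keep = ld_prune(
        inst.rename(columns={"SNP": "variant_id", "p_exposure": "p"})[["variant_id", "p"]],
        ld,
        r2_max=clump_r2,
    )
    return inst[inst["SNP"].isin(keep)].reset_index(drop=True)


def wald_ratio(inst: pd.Series | pd.DataFrame, aptamer_id: str = "", configuration: str = "all") -> MrResult:
    """Single-instrument causal estimate: beta_outcome / beta_exposure with
    the first-order delta standard error se_outcome / |beta_exposure|."""
    if isinstance(inst, pd.DataFrame):
        if len(inst) != 1:
            raise ValueError(f"wald_ratio needs exactly one instrument, got {len(inst)}")
        inst = inst.iloc[0]
    bx = float(inst["beta_exposure"])
    if abs(bx) < 1e-12:
        raise ValueError("exposure effect is numerically zero; Wald ratio undefined")
    theta = float(inst["beta_outcome"]) / bx
    se = float(inst["se_outcome"]) / abs(bx)
    z = theta / se
    return MrResult(aptamer_id, "wald", 1, theta, se, float(2 * stats.norm.sf(abs(z))), configuration)


def ivw(instruments: pd.DataFrame, aptamer_id: str = "", configuration: str = "all") -> MrResult:
    """Fixed-effect inverse-variance-weighted estimate: weighted regression
    of beta_outcome on beta_exposure through the origin with weights
    1/se_outcome^2.  Delegates to the Wald ratio for one instrument."""
    if len(instruments) == 0:
        return MrResult(aptamer_id, "none", 0, np.nan, np.nan, np.nan, configuration)
    if len(instruments) == 1:
        return wald_ratio(instruments, aptamer_id, configuration)
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    w = 1.0 / instruments["se_outcome"].to_numpy(dtype=float) ** 2
    denom = float((w * bx**2).sum())
    theta = float((w * bx * by).sum()) / denom
    se = float(np.sqrt(1.0 / denom))
    z = theta / se
    return MrResult(
        aptamer_id, "ivw", len(instruments), theta, se, float(2 * stats.norm.sf(abs(z))), configuration
    )


def sensitivity_configs(
    aptamer_id: str,
    instruments: pd.DataFrame,
    exclude_region: tuple[str, float, float] = ("12", 39e6, 41.5e6),
    gene_region: tuple[str, float, float] | None = None,
    cis_window: float = 1e6,
) -> dict[str, MrResult]:
    """Run the three MR configurations for one aptamer.

    'all' uses every instrument; 'exclude_region' drops instruments inside
    the (chrom, start, end) pleiotropic region; 'cis_only' keeps
    instruments within ``cis_window`` of the aptamer's gene coding span
    (skipped with an empty result when the gene region is unknown).
    """
    results = {"all": ivw(instruments, aptamer_id, "all")}
    chrom, lo, hi = exclude_region
    inside = (
        (instruments["CHR"].astype(str) == str(chrom))
        & (instruments["POS"] >= lo)
        & (instruments["POS"] <= hi)
    )
    results["exclude_region"] = ivw(
        instruments[~inside].reset_index(drop=True), aptamer_id, "exclude_region"
    )
    if gene_region is None:
        results["cis_only"] = MrResult(aptamer_id, "none", 0, np.nan, np.nan, np.nan, "cis_only")
    else:
        gchrom, gstart, gend = gene_region
        cis = (
            (instruments["CHR"].astype(str) == str(gchrom))
            & (instruments["POS"] >= gstart - cis_window)
            & (instruments["POS"] <= gend + cis_window)
        )
        results["cis_only"] = ivw(instruments[cis].reset_index(drop=True), aptamer_id, "cis_only")
    return results
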
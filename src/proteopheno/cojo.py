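"""Conditional and joint SNP selection from summary statistics, PheWAS
with FDR control, LD pruning, and the iterated sentinel-SNP discovery loop.

The conditional machinery reconstructs the multiple-regression system from
marginal per-allele betas, their standard errors, per-variant dosage
standard deviations and the LD (genotype correlation) matrix.  When the LD
matrix is computed in-sample — from the same genotypes that produced the
marginal statistics — the joint estimates equal individual-level multiple
regression exactly, which is what the recovery tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeMatrix

__all__ = [
    "LdMatrix",
    "SelectionResult",
    "phewas",
    "conditional_stats",
    "stepwise_select",
    "ld_prune",
    "discovery_loop",
]


@dataclass
class LdMatrix:
    """Pairwise genotype correlation with per-variant scale information.

    r: correlation DataFrame (symmetric, unit diagonal); sd: sample
    standard deviation (ddof=1) of each variant's dosage; n: sample size
    of the LD reference.
    """

    r: pd.DataFrame
    sd: pd.Series
    n: int

    def __post_init__(self) -> None:
        if not self.r.index.equals(self.r.columns):
            raise ValueError("LD matrix must have identical row and column variant IDs")
        arr = self.r.to_numpy()
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if np.nanmax(np.abs(arr)) > 1 + 1e-8:
            raise ValueError("LD entries must satisfy |r| <= 1")

    @classmethod
    def from_genotypes(cls, genotypes: GenotypeMatrix) -> "LdMatrix":
        dos = genotypes.dosages
        return cls(r=dos.corr(), sd=dos.std(ddof=1), n=len(dos))

    def r2(self) -> pd.DataFrame:
        return self.r**2

    def subset(self, ids) -> "LdMatrix":
        ids = list(ids)
        return LdMatrix(self.r.loc[ids, ids], self.sd.loc[ids], self.n)


def phewas(
    variant_id: str, records: pd.DataFrame, fdr_level: float = 0.05
) -> pd.DataFrame:
    """Benjamini-Hochberg FDR across all aptamers for one query variant.

    records: association table with one row per aptamer for ``variant_id``
    (columns aptamer_id, p at minimum).  Returns aptamers with q <= level,
    sorted by raw p, with their q-values.
    """
    sub = records[records["variant_id"] == variant_id] if "variant_id" in records else records
    sub = sub.dropna(subset=["p"])
    if sub.empty:
        return pd.DataFrame(columns=["aptamer_id", "p", "q", "significant"])
    _, q, _, _ = multipletests(sub["p"].to_numpy(), method="fdr_bh")
    out = sub[["aptamer_id", "p"]].copy()
    out["q"] = q
    out["significant"] = out["q"] <= fdr_level
    out = out.sort_values(["p", "aptamer_id"]).reset_index(drop=True)
    return out[out["significant"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# summary-statistic joint modelling


def _standardize(marginal: pd.DataFrame, ld: LdMatrix) -> tuple[pd.Series, float, pd.Series]:
    """Recover correlation-scale effects r_gy and the phenotype sd from
    per-allele marginal statistics.

    Uses the single-SNP OLS identities sd_y^2 = sd_g^2 (beta^2 + se^2 (n-2))
    and r_gy = beta sd_g / sd_y; sd_y is pooled as the median implied value
    across SNPs (they agree exactly on complete-case data).
    """
    m = marginal.set_index("variant_id")
    ids = m.index
    sd_g = ld.sd.loc[ids]
    n = m["n"].astype(float)
    sd_y2 = sd_g**2 * (m["beta"] ** 2 + m["se"] ** 2 * (n - 2))
    sd_y = float(np.sqrt(np.median(sd_y2)))
    r_gy = m["beta"] * sd_g / sd_y
    return r_gy, sd_y, sd_g


def _joint_fit(
    ids: list[str],
    r_gy: pd.Series,
    sd_y: float,
    sd_g: pd.Series,
    ld: LdMatrix,
    n: int,
) -> pd.DataFrame:
    """Joint per-allele betas/ses/ps for the SNP set ``ids`` from summary
    moments; equals multiple regression with intercept on in-sample data."""
    R = ld.r.loc[ids, ids].to_numpy()
    r = r_gy.loc[ids].to_numpy()
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e10:
        raise np.linalg.LinAlgError(
            f"singular LD submatrix for variants {ids} (condition number {cond:.3g})"
        )
    Rinv = np.linalg.inv(R)
    b_std = Rinv @ r
    df = n - len(ids) - 1
    if df <= 0:
        raise ValueError("joint model has nonpositive residual degrees of freedom")
    sigma2_std = max(1.0 - float(b_std @ r), 0.0) * (n - 1) / df
    var_std = sigma2_std * np.diag(Rinv) / (n - 1)
    beta = b_std * sd_y / sd_g.loc[ids].to_numpy()
    se = np.sqrt(var_std) * sd_y / sd_g.loc[ids].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"variant_id": ids, "beta_joint": beta, "se_joint": se, "p_joint": p}
    )


def conditional_stats(
    marginal: pd.DataFrame,
    ld: LdMatrix,
    conditioning: list[str],
    collinearity: float = 0.9,
) -> pd.DataFrame:
    """Per-SNP effects conditional on a fixed SNP set.

    For each free SNP the joint model over {conditioning + SNP} is solved
    and the SNP's joint coefficient reported.  A SNP that is itself in the
    conditioning set gets conditional beta 0 with a 'self' flag; a SNP too
    collinear with the set (any r^2 >= ``collinearity``) is flagged and
    skipped.
    """
    conditioning = list(conditioning)
    missing = [v for v in conditioning if v not in ld.r.index]
    if missing:
        raise KeyError(f"conditioning variants missing from LD: {missing}")
    r_gy, sd_y, sd_g = _standardize(marginal, ld)
    n = int(marginal["n"].median())
    rows = []
    for vid in marginal["variant_id"]:
        if vid in conditioning:
            rows.append((vid, 0.0, np.nan, np.nan, "self"))
            continue
        if conditioning:
            r2max = float((ld.r.loc[vid, conditioning] ** 2).max())
            if r2max >= collinearity:
                rows.append((vid, np.nan, np.nan, np.nan, "collinear"))
                continue
        fit = _joint_fit(conditioning + [vid], r_gy, sd_y, sd_g, ld, n)
        last = fit.iloc[-1]
        rows.append((vid, last["beta_joint"], last["se_joint"], last["p_joint"], ""))
    return pd.DataFrame(
        rows, columns=["variant_id", "beta_cond", "se_cond", "p_cond", "flag"]
    )


@dataclass
class SelectionResult:
    """Outcome of stepwise conditional-joint selection for one aptamer."""

    aptamer_id: str
    selected: pd.DataFrame  # variant_id, beta_joint, se_joint, p_joint
    trace: list[dict] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.selected["variant_id"])


def stepwise_select(
    marginal: pd.DataFrame,
    ld: LdMatrix,
    p_entry: float = 5e-8,
    collinearity: float = 0.9,
    aptamer_id: str = "",
    max_iter: int = 100,
) -> SelectionResult:
    """Greedy forward selection of independently associated SNPs from
    summary statistics, with a backward check after each addition.

    Entry is by smallest conditional p below ``p_entry`` (ties broken by
    smallest p then lexicographic variant ID); after each addition the
    joint model is refitted and any selected SNP whose joint p exceeds
    ``p_entry`` is dropped.  Terminates when no free SNP qualifies.
    """
    marginal = marginal.dropna(subset=["beta", "se", "p"]).reset_index(drop=True)
    r_gy, sd_y, sd_g = _standardize(marginal, ld)
    n = int(marginal["n"].median())
    trace: list[dict] = []
    selected: list[str] = []
    for _ in range(max_iter):
        cond = conditional_stats(marginal, ld, selected, collinearity)
        free = cond[(cond["flag"] == "") & (cond["p_cond"] < p_entry)]
        if free.empty:
            break
        free = free.sort_values(["p_cond", "variant_id"])
        add = free.iloc[0]["variant_id"]
        selected.append(add)
        trace.append({"action": "add", "variant_id": add, "p_cond": float(free.iloc[0]["p_cond"])})
        # backward check on the refitted joint model
        while len(selected) > 1:
            fit = _joint_fit(selected, r_gy, sd_y, sd_g, ld, n)
            worst = fit.sort_values("p_joint", ascending=False).iloc[0]
            if worst["p_joint"] > p_entry:
                selected.remove(worst["variant_id"])
                trace.append(
                    {"action": "drop", "variant_id": worst["variant_id"], "p_joint": float(worst["p_joint"])}
                )
            else:
                break
    if selected:
        final = _joint_fit(selected, r_gy, sd_y, sd_g, ld, n)
    else:
        final = pd.DataFrame(columns=["variant_id", "beta_joint", "se_joint", "p_joint"])
    return SelectionResult(aptamer_id=aptamer_id, selected=final, trace=trace)


def ld_prune(
    variants: pd.DataFrame, ld: LdMatrix, r2_max: float = 0.85
) -> list[str]:
    """Greedy keep-best-p pruning: walk variants by ascending p and drop
    any variant with r^2 strictly above ``r2_max`` to an already-kept one.

    variants: DataFrame with variant_id and p columns.
    """
    order = variants.dropna(subset=["p"]).sort_values(["p", "variant_id"])
    kept: list[str] = []
    for vid in order["variant_id"]:
        if vid not in ld.r.index:
            raise KeyError(f"variant {vid} missing from LD matrix")
        # tolerance: a pair at exactly the boundary (e.g. r = sqrt(0.85))
        # must be kept despite float rounding
        if all(ld.r.loc[vid, k] ** 2 <= r2_max + 1e-12 for k in kept):
            kept.append(vid)
    return kept


def discovery_loop(
    sentinel: str,
    assoc: pd.DataFrame,
    ld: LdMatrix,
    fdr_level: float = 0.05,
    p_entry: float = 5e-8,
    r2_prune: float = 0.85,
    rounds: int = 2,
) -> dict:
    """Iterated sentinel-SNP discovery: PheWAS of the sentinel, stepwise
    conditional selection per significant aptamer, LD pruning of the SNP
    union, then a PheWAS of each surviving SNP to pick up further aptamers.

    assoc: full association table (variant_id, aptamer_id, beta, se, p, n).
    Returns a dict with 'variants', 'aptamers', per-round details and the
    per-aptamer selection traces.
    """
    aptamers: set[str] = set()
    snps: set[str] = {sentinel}
    selections: dict[str, SelectionResult] = {}
    round_log = []
    query_snps = [sentinel]
    for rnd in range(rounds):
        new_apts: set[str] = set()
        for snp in query_snps:
            hits = phewas(snp, assoc[assoc["variant_id"] == snp], fdr_level)
            new_apts.update(hits["aptamer_id"])
        new_apts -= aptamers
        aptamers |= new_apts
        for apt in sorted(new_apts):
            marg = assoc[assoc["aptamer_id"] == apt]
            sel = stepwise_select(marg, ld, p_entry=p_entry, aptamer_id=apt)
            selections[apt] = sel
            snps.update(sel.variant_ids)
        # prune the SNP union by each SNP's best p across discovered aptamers
        pool = assoc[assoc["variant_id"].isin(snps) & assoc["aptamer_id"].isin(aptamers)]
        best_p = pool.groupby("variant_id")["p"].min().reset_index()
        kept = ld_prune(best_p.rename(columns={"p": "p"}), ld, r2_prune) if not best_p.empty else []
        # the sentinel's proxies may outrank it; keep the pruned set
        snps = set(kept) if kept else snps
        round_log.append({"round": rnd, "new_aptamers": sorted(new_apts), "snps": sorted(snps)})
        query_snps = sorted(snps - {sentinel}) if rnd == 0 else sorted(snps)
        if not new_apts and rnd > 0:
            break
    return {
        "variants": sorted(snps),
        "aptamers": sorted(aptamers),
        "selections": selections,
        "rounds": round_log,
    }
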
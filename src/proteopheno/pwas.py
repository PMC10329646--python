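"""Proteome-wide association: per-aptamer SNP weight models over cis+trans
SNP sets and the weighted association statistic against GWAS z-scores.

The association statistic is the standard weighted z combination
``z = w'z_gwas / sqrt(w' R w)`` where R is the LD (genotype correlation)
matrix over the weight SNPs; under the null of no association between the
predicted protein and the trait it is standard normal.  Weight models are
the minimal pair: the single best SNP ("top1", weight = marginal beta) and
an elastic net; whichever has the higher k-fold cross-validated R^2 is
retained, and a model whose cv R^2 is not positive is unusable (its
protein is excluded from the PWAS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .cojo import LdMatrix

__all__ = ["WeightModel", "PwasResult", "train_weights", "pwas_assoc", "postprocess_loci"]


@dataclass
class WeightModel:
    """Per-aptamer SNP weight vector with cross-validation metadata."""

    aptamer_id: str
    weights: pd.Series  # variant_id -> weight (per alt-allele dosage)
    model: str  # "top1" | "enet"
    cv_r2: float
    cv_r2_p: float
    usable: bool
    snp_tags: dict[str, str] = field(default_factory=dict)  # variant_id -> cis|trans

    def nonzero(self) -> pd.Series:
        return self.weights[self.weights != 0.0]


def _oof_r2(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    if r2 <= 0:
        return r2, 1.0
    r = np.corrcoef(y, pred)[0, 1]
    n = len(y)
    t = r * np.sqrt((n - 2) / max(1e-12, 1 - r**2))
    return r2, float(2.0 * stats.t.sf(abs(t), n - 2))


def train_weights(
    genotypes: pd.DataFrame,
    protein: pd.Series,
    snp_set: list[str] | None = None,
    folds: int = 5,
    snp_tags: dict[str, str] | None = None,
    seed: int = 0,
) -> WeightModel:
    """Fit top1 and elastic-net weight models and keep the better by
    out-of-fold R^2.

    genotypes: samples x variants dosage frame; protein: covariate-residualized
    levels aligned on samples; snp_set: the cis-window plus conditionally
    selected trans SNPs to consider.
    """
    if snp_set is not None:
        genotypes = genotypes[list(snp_set)]
    common = genotypes.index.intersection(protein.index)
    X = genotypes.loc[common].to_numpy(dtype=float)
    y = protein.loc[common].to_numpy(dtype=float)
    n = len(common)
    if n < folds * 5:
        raise ValueError(f"{n} samples is too few for {folds}-fold weight training")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    Xc = X - X.mean(axis=0)
    pred_top1 = np.empty(n)
    for tr, te in kf.split(X):
        xt, yt = X[tr], y[tr]
        sd = xt.std(axis=0)
        sd[sd == 0] = np.inf
        r = ((xt - xt.mean(0)) * (yt - yt.mean())[:, None]).sum(0) / (len(tr) * sd * yt.std())
        j = int(np.argmax(np.abs(r)))
        slope = np.polyfit(xt[:, j], yt, 1)
        pred_top1[te] = np.polyval(slope, X[te, j])
    r2_top1, p_top1 = _oof_r2(y, pred_top1)

    # choose the penalty once by inner CV, then score honestly out of fold
    enet_cv = ElasticNetCV(l1_ratio=0.5, cv=folds, random_state=seed, alphas=30, max_iter=5000)
    with np.errstate(all="ignore"):
        enet_cv.fit(Xc, y - y.mean())
    pred_enet = np.empty(n)
    for tr, te in kf.split(X):
        model = ElasticNet(alpha=enet_cv.alpha_, l1_ratio=0.5, max_iter=5000)
        model.fit(X[tr], y[tr])
        pred_enet[te] = model.predict(X[te])
    r2_enet, p_enet = _oof_r2(y, pred_enet)

    if r2_top1 >= r2_enet:
        # final top1: best SNP on the full data, weight = marginal beta
        sd = X.std(axis=0)
        sd[sd == 0] = np.inf
        r = (Xc * (y - y.mean())[:, None]).sum(0) / (n * sd * y.std())
        j = int(np.argmax(np.abs(r)))
        beta = np.polyfit(X[:, j], y, 1)[0]
        w = pd.Series(0.0, index=genotypes.columns)
        w.iloc[j] = beta
        tag, r2, p = "top1", r2_top1, p_top1
    else:
        model = ElasticNet(alpha=enet_cv.alpha_, l1_ratio=0.5, max_iter=5000)
        model.fit(X, y)
        w = pd.Series(model.coef_, index=genotypes.columns)
        tag, r2, p = "enet", r2_enet, p_enet
    # a usable model needs genuinely predictive weights: positive
    # out-of-fold R^2 whose prediction-observation correlation is also
    # nominally significant (the heritability screen of weight-based
    # association frameworks)
    usable = r2 > 0 and p < 0.05 and (w != 0).any()
    return WeightModel(
        aptamer_id=str(protein.name) if protein.name else "",
        weights=w,
        model=tag,
        cv_r2=r2,
        cv_r2_p=p,
        usable=bool(usable),
        snp_tags=dict(snp_tags or {}),
    )


@dataclass
class PwasResult:
    aptamer_id: str
    z: float
    p: float
    n_snp: int
    locus: int | None = None
    flag: str = ""


def pwas_assoc(
    model: WeightModel,
    gwas: pd.DataFrame,
    ld: LdMatrix,
    eig_floor: float = 1e-8,
) -> PwasResult:
    """Weighted association statistic of a predicted protein with the trait.

    gwas: summary table with SNP, A1, A2, BETA, SE columns; z-scores are
    harmonized to the weight model's alt-allele orientation (variant IDs
    are chrom:pos:ref:alt, so the model's effect allele is the ID's alt).
    R is regularized by flooring its eigenvalues at ``eig_floor``.
    """
    w = model.nonzero()
    if w.empty or not model.usable:
        return PwasResult(model.aptamer_id, np.nan, np.nan, 0, flag="unusable_model")
    g = gwas.set_index("SNP")
    missing = [v for v in w.index if v not in g.index]
    if missing:
        return PwasResult(model.aptamer_id, np.nan, np.nan, len(w), flag=f"missing_gwas:{missing[:3]}")
    z = (g.loc[w.index, "BETA"] / g.loc[w.index, "SE"]).to_numpy(dtype=float)
    alt = pd.Index(w.index).str.split(":").str[3]
    flip = (g.loc[w.index, "A1"].to_numpy() != alt.to_numpy())
    z = np.where(flip, -z, z)
    R = ld.r.loc[w.index, w.index].to_numpy()
    vals, vecs = np.linalg.eigh(R)
    R = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    wv = w.to_numpy()
    denom = float(wv @ R @ wv)
    if denom <= 0:
        return PwasResult(model.aptamer_id, np.nan, np.nan, len(w), flag="nonpositive_variance")
    z_pwas = float(wv @ z / np.sqrt(denom))
    p = float(2.0 * stats.norm.sf(abs(z_pwas)))
    return PwasResult(model.aptamer_id, z_pwas, p, len(w))


def _predicted_corr(wi: pd.Series, wj: pd.Series, ld: LdMatrix) -> float:
    ids = sorted(set(wi.index) | set(wj.index))
    R = ld.r.loc[ids, ids].to_numpy()
    a = wi.reindex(ids, fill_value=0.0).to_numpy()
    b = wj.reindex(ids, fill_value=0.0).to_numpy()
    denom = np.sqrt((a @ R @ a) * (b @ R @ b))
    return float(a @ R @ b / denom) if denom > 0 else 0.0


def postprocess_loci(
    results: list[PwasResult],
    models: dict[str, WeightModel],
    positions: pd.Series,
    ld: LdMatrix,
    window: int = 100_000,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Group significant features into loci and flag conditionally
    independent ones.

    Features pass BH at ``fdr_level`` across all tested aptamers; each
    significant feature's span is the position range of its nonzero-weight
    SNPs, and spans that come within ``window`` bp are merged into one
    locus.  Within a locus, features are taken strongest-|z| first and each
    subsequent feature's z is conditioned on the already-accepted ones via
    the correlation of their genetically predicted protein levels; features
    whose conditional |z| stays above the two-sided 0.05 normal cutoff are
    flagged conditionally independent.
    """
    tab = pd.DataFrame(
        [(r.aptamer_id, r.z, r.p, r.n_snp, r.flag) for r in results],
        columns=["aptamer_id", "z", "p", "n_snp", "flag"],
    )
    ok = tab["p"].notna()
    tab["q"] = np.nan
    if ok.any():
        _, q, _, _ = multipletests(tab.loc[ok, "p"].to_numpy(), method="fdr_bh")
        tab.loc[ok, "q"] = q
    tab["significant"] = tab["q"] <= fdr_level
    tab["locus"] = pd.array([None] * len(tab), dtype="Int64")
    tab["conditionally_independent"] = False
    tab["z_conditional"] = np.nan

    sig = tab[tab["significant"]].copy()
    if sig.empty:
        return tab
    spans = {}
    for apt in sig["aptamer_id"]:
        snps = models[apt].nonzero().index
        pos = positions.loc[snps]
        spans[apt] = (float(pos.min()), float(pos.max()))
    sig = sig.assign(
        start=[spans[a][0] for a in sig["aptamer_id"]],
        end=[spans[a][1] for a in sig["aptamer_id"]],
    ).sort_values("start")
    locus_id, cur_end = -1, -np.inf
    assignment = {}
    for _, row in sig.iterrows():
        if row["start"] > cur_end + window:
            locus_id += 1
            cur_end = row["end"]
        else:
            cur_end = max(cur_end, row["end"])
        assignment[row["aptamer_id"]] = locus_id
    for apt, loc in assignment.items():
        tab.loc[tab["aptamer_id"] == apt, "locus"] = loc

    for loc in sorted(set(assignment.values())):
        members = sig[sig["aptamer_id"].map(assignment) == loc]
        members = members.assign(_absz=members["z"].abs()).sort_values(
            ["_absz", "aptamer_id"], ascending=[False, True]
        )
        kept: list[str] = []
        for _, row in members.iterrows():
            apt = row["aptamer_id"]
            if not kept:
                z_cond = row["z"]
            else:
                rk = np.array([_predicted_corr(models[apt].nonzero(), models[k].nonzero(), ld) for k in kept])
                Rkk = np.array(
                    [[_predicted_corr(models[a].nonzero(), models[b].nonzero(), ld) for b in kept] for a in kept]
                )
                zk = np.array([float(tab.loc[tab["aptamer_id"] == k, "z"].iloc[0]) for k in kept])
                sol = np.linalg.solve(Rkk + 1e-10 * np.eye(len(kept)), rk)
                var = 1.0 - float(rk @ sol)
                if var < 1e-6:
                    # predicted level fully explained by accepted features
                    tab.loc[tab["aptamer_id"] == apt, ["z_conditional", "conditionally_independent"]] = [0.0, False]
                    continue
                z_cond = float((row["z"] - sol @ zk) / np.sqrt(var))
            indep = abs(z_cond) > stats.norm.isf(0.025)
            tab.loc[tab["aptamer_id"] == apt, ["z_conditional", "conditionally_independent"]] = [z_cond, indep]
            if indep:
                kept.append(apt)
    return tab
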
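"""Covariate-adjusted SNP-aptamer association scanning and fixed-effect
inverse-variance meta-analysis with Cochran's Q / I^2 heterogeneity.

The per-cohort scan regresses each normalized aptamer level on each
variant's alternate-allele dosage plus covariates (age, sex, genotype
principal components, genotyping array), reporting beta in SD-protein per
effect allele.  Identical betas and standard errors come out of the
Frisch-Waugh-Lovell residualization used here and a full design-matrix
least squares; p-values use the t distribution with the residual degrees
of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix, ProteinMatrix

__all__ = [
    "compute_pcs",
    "build_covariate_design",
    "linear_scan",
    "meta_fixed",
    "forest_consistency",
]

ASSOC_COLUMNS = [
    "variant_id",
    "aptamer_id",
    "beta",
    "se",
    "t",
    "p",
    "n",
    "effect_allele",
    "effect_allele_freq",
    "flag",
]


def compute_pcs(genotypes: GenotypeMatrix, n_pcs: int = 10) -> pd.DataFrame:
    """Principal components of the (mean-imputed, centered) dosage matrix."""
    X = genotypes.dosages.to_numpy(dtype=float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    n_pcs = min(n_pcs, min(X.shape) - 1)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(
        pcs, index=genotypes.dosages.index, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )


def build_covariate_design(
    covariates: pd.DataFrame,
    pcs: pd.DataFrame | None = None,
    include: tuple[str, ...] = ("age", "sex", "array"),
) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) from a covariate table.

    Categorical 'array' expands to treatment-coded indicators.  Genotype
    PCs are appended when given.
    """
    parts = []
    if "age" in include and "age" in covariates:
        parts.append(covariates[["age"]].astype(float))
    if "sex" in include and "sex" in covariates:
        parts.append(covariates[["sex"]].astype(float))
    if "array" in include and "array" in covariates:
        dummies = pd.get_dummies(covariates["array"], prefix="array", drop_first=True)
        parts.append(dummies.astype(float))
    if pcs is not None:
        parts.append(pcs)
    if not parts:
        return pd.DataFrame(index=covariates.index)
    design = pd.concat(parts, axis=1)
    return design.loc[covariates.index]


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of M on [1, C] via least squares."""
    X = np.column_stack([np.ones(len(C)), C])
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ coef


def linear_scan(
    genotypes: GenotypeMatrix,
    proteins: ProteinMatrix,
    covariates: pd.DataFrame | None = None,
    n_pcs: int = 10,
    min_n: int = 30,
) -> pd.DataFrame:
    """OLS of each aptamer on each variant's dosage plus covariates.

    Samples are intersected across the three inputs; missing dosage or
    protein values are handled per-pair complete-case.  A variant with
    zero dosage variance yields a record with NA statistics and a
    'zero_variance' flag.
    """
    common = genotypes.dosages.index.intersection(proteins.values.index)
    if covariates is not None:
        covariates = covariates.loc[covariates.index.intersection(common)].dropna()
        common = common.intersection(covariates.index)
    if len(common) < min_n:
        raise ValueError(f"only {len(common)} overlapping complete-case samples")
    G = genotypes.dosages.loc[common]
    Y = proteins.values.loc[common]
    if covariates is not None:
        pcs = compute_pcs(
            GenotypeMatrix(G, genotypes.variants, genotypes.samples.loc[common]), n_pcs
        ) if n_pcs > 0 else None
        Cdf = build_covariate_design(covariates.loc[common], pcs)
        C = Cdf.to_numpy(dtype=float)
    else:
        C = np.empty((len(common), 0))
    q = C.shape[1] + 1  # covariates + intercept

    freq = (G.mean(axis=0) / 2.0).to_numpy()
    alt = genotypes.variants["alt"].reindex(G.columns).to_numpy()
    Garr = G.to_numpy(dtype=float)
    Yarr = Y.to_numpy(dtype=float)
    g_has_nan = np.isnan(Garr).any(axis=0)
    records: list[tuple] = []

    # per-aptamer complete-case, vectorized across all fully observed variants
    full_cache: tuple[np.ndarray, np.ndarray] | None = None
    clean = ~g_has_nan
    for k, apt in enumerate(Y.columns):
        y = Yarr[:, k]
        mask = ~np.isnan(y)
        n = int(mask.sum())
        if n < q + 3:
            for j in np.nonzero(clean)[0]:
                records.append(
                    (G.columns[j], apt, np.nan, np.nan, np.nan, np.nan, n, alt[j], freq[j], "too_few_samples")
                )
            continue
        if mask.all():
            if full_cache is None:
                full_cache = (
                    _residualize(Garr[:, clean], C),
                    None,  # y residuals are per-aptamer
                )
            Gr = full_cache[0]
            Cm = C
        else:
            Gr = _residualize(Garr[mask][:, clean], C[mask])
            Cm = C[mask]
        yr = _residualize(y[mask][:, None], Cm)[:, 0]
        gss = (Gr**2).sum(axis=0)
        df = n - q - 1
        ok = gss > 1e-12
        beta = np.full(gss.shape, np.nan)
        se = np.full(gss.shape, np.nan)
        beta[ok] = (Gr[:, ok] * yr[:, None]).sum(axis=0) / gss[ok]
        rss = (yr @ yr) - beta**2 * gss
        with np.errstate(invalid="ignore", divide="ignore"):
            se[ok] = np.sqrt(np.maximum(rss[ok], 0.0) / df / gss[ok])
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        for idx, j in enumerate(np.nonzero(clean)[0]):
            if ok[idx]:
                records.append((G.columns[j], apt, beta[idx], se[idx], t[idx], p[idx], n, alt[j], freq[j], ""))
            else:
                records.append(
                    (G.columns[j], apt, np.nan, np.nan, np.nan, np.nan, n, alt[j], freq[j], "zero_variance")
                )

    # variants with missing dosages: per-pair complete-case fallback
    for j in np.nonzero(g_has_nan)[0]:
        g = Garr[:, j]
        vid = G.columns[j]
        for k, apt in enumerate(Y.columns):
            y = Yarr[:, k]
            mask = ~(np.isnan(g) | np.isnan(y))
            n = int(mask.sum())
            gm = g[mask]
            if n < q + 3 or gm.var() <= 1e-12:
                records.append(
                    (vid, apt, np.nan, np.nan, np.nan, np.nan, n, alt[j], freq[j], "zero_variance")
                )
                continue
            X = np.column_stack([np.ones(n), gm, C[mask]])
            ym = y[mask]
            coef, _, _, _ = np.linalg.lstsq(X, ym, rcond=None)
            resid = ym - X @ coef
            df = n - X.shape[1]
            sigma2 = resid @ resid / df
            xtx_inv = np.linalg.inv(X.T @ X)
            se_1 = np.sqrt(sigma2 * xtx_inv[1, 1])
            t_1 = coef[1] / se_1
            p_1 = 2.0 * stats.t.sf(np.abs(t_1), df)
            records.append((vid, apt, coef[1], se_1, t_1, p_1, n, alt[j], freq[j], ""))
    out = pd.DataFrame(records, columns=ASSOC_COLUMNS)
    return out.sort_values(["variant_id", "aptamer_id"], kind="stable").reset_index(drop=True)


def meta_fixed(cohort_records: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis per (variant, aptamer).

    Alleles are harmonized to the effect allele of the first cohort
    reporting the pair (beta sign and frequency flipped for swapped
    orientations).  Returns beta_meta, se_meta, p_meta, Cochran's Q,
    I^2 (percent) and a +/-/? direction string in cohort order.
    """
    cohorts = list(cohort_records)
    pieces = []
    for name, rec in cohort_records.items():
        r = rec.copy()
        r["cohort"] = name
        pieces.append(r)
    allrec = pd.concat(pieces, ignore_index=True)
    out = []
    for (vid, apt), grp in allrec.groupby(["variant_id", "aptamer_id"], sort=True):
        grp = grp.set_index("cohort").reindex(cohorts)
        ref_allele = None
        betas, ses, direction = [], [], []
        for name in cohorts:
            row = grp.loc[name]
            if not np.isfinite(row.get("beta", np.nan)) or not np.isfinite(row.get("se", np.nan)):
                if row.notna().any():
                    direction.append("?")
                continue
            b = float(row["beta"])
            if ref_allele is None:
                ref_allele = row["effect_allele"]
            elif row["effect_allele"] != ref_allele:
                b = -b
            betas.append(b)
            ses.append(float(row["se"]))
            direction.append("+" if b > 0 else ("-" if b < 0 else "0"))
        if not betas:
            out.append((vid, apt, np.nan, np.nan, np.nan, np.nan, np.nan, "".join(direction), 0, ref_allele))
            continue
        b = np.array(betas)
        w = 1.0 / np.array(ses) ** 2
        beta_meta = float((w * b).sum() / w.sum())
        se_meta = float(np.sqrt(1.0 / w.sum()))
        z = beta_meta / se_meta
        p_meta = float(2.0 * stats.norm.sf(abs(z)))
        Q = float((w * (b - beta_meta) ** 2).sum())
        k = len(b)
        i2 = 0.0 if (k < 2 or Q <= 0) else max(0.0, (Q - (k - 1)) / Q) * 100.0
        out.append((vid, apt, beta_meta, se_meta, p_meta, Q, i2, "".join(direction), k, ref_allele))
    return pd.DataFrame(
        out,
        columns=[
            "variant_id",
            "aptamer_id",
            "beta_meta",
            "se_meta",
            "p_meta",
            "Q",
            "I2",
            "direction",
            "n_cohorts",
            "effect_allele",
        ],
    )


def forest_consistency(
    cohort_records: dict[str, pd.DataFrame],
    meta: pd.DataFrame,
    i2_flag: float = 50.0,
) -> pd.DataFrame:
    """Cross-cohort consistency per pair: sign concordance with the meta
    direction and an I^2 heterogeneity flag (> ``i2_flag`` percent)."""
    rows = []
    for _, m in meta.iterrows():
        signs = [c for c in m["direction"] if c in "+-"]
        if not signs or not np.isfinite(m["beta_meta"]):
            rows.append((m["variant_id"], m["aptamer_id"], np.nan, False))
            continue
        meta_sign = "+" if m["beta_meta"] > 0 else "-"
        concord = sum(1 for s in signs if s == meta_sign) / len(signs)
        rows.append(
            (m["variant_id"], m["aptamer_id"], concord, bool(m["I2"] > i2_flag))
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "aptamer_id", "sign_concordance", "heterogeneity_flag"]
    )
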
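"""Observational group comparisons of normalized protein levels.

Covers the validation-style contrasts: control vs case / prodromal /
mutation-carrier groups, and male vs female within strata, each as a
covariate-adjusted linear model per aptamer with Benjamini-Hochberg FDR
across aptamers within the contrast.  With no covariates the group
contrast reduces exactly to an equal-variance two-sample t-test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["group_compare", "sex_difference"]

CONTRAST_COLUMNS = [
    "aptamer_id",
    "contrast",
    "effect",
    "se",
    "p",
    "q",
    "n_reference",
    "n_comparison",
]


def _ols_contrast(y: np.ndarray, g: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    X = np.column_stack([np.ones(len(y)), g, C])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = coef[1] / se
    return float(coef[1]), se, float(2 * stats.t.sf(abs(t), df))


def group_compare(
    proteins: pd.DataFrame,
    phenotypes: pd.DataFrame,
    contrast: tuple[str, str],
    group_column: str = "diagnosis",
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-aptamer adjusted difference between two phenotype groups.

    contrast = (reference, comparison); the reported effect is the mean
    shift of the comparison group in SD-protein units after covariate
    adjustment.  Groups with fewer than 2 samples skip the contrast with a
    warning (empty result).
    """
    ref, comp = contrast
    labels = phenotypes[group_column]
    ref_ids = phenotypes.index[labels == ref]
    comp_ids = phenotypes.index[labels == comp]
    if len(ref_ids) < 2 or len(comp_ids) < 2:
        warnings.warn(f"contrast {ref}_vs_{comp}: a group has <2 samples, skipped")
        return pd.DataFrame(columns=CONTRAST_COLUMNS)
    ids = ref_ids.append(comp_ids).intersection(proteins.index)
    if covariates is not None:
        cov = covariates.loc[covariates.index.intersection(ids)].dropna()
        ids = ids.intersection(cov.index)
        C = cov.loc[ids].to_numpy(dtype=float)
    else:
        C = np.empty((len(ids), 0))
    g = labels.loc[ids].eq(comp).to_numpy(dtype=float)
    rows = []
    name = f"{ref}_vs_{comp}"
    for apt in proteins.columns:
        y = proteins.loc[ids, apt]
        mask = y.notna().to_numpy()
        if mask.sum() < C.shape[1] + 4 or len(np.unique(g[mask])) < 2:
            continue
        eff, se, p = _ols_contrast(y.to_numpy(dtype=float)[mask], g[mask], C[mask])
        rows.append((apt, name, eff, se, p, np.nan, int((g[mask] == 0).sum()), int((g[mask] == 1).sum())))
    out = pd.DataFrame(rows, columns=CONTRAST_COLUMNS)
    if not out.empty:
        _, q, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["q"] = q
    return out


def sex_difference(
    proteins: pd.DataFrame,
    phenotypes: pd.DataFrame,
    strata: dict[str, pd.Index] | None = None,
    sex_column: str = "sex",
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Male-vs-female contrast per stratum, adjusted for the given
    covariates (sex itself must not be among them); BH within stratum.

    strata maps stratum name -> sample index; default is one 'all' stratum.
    Sex coding: 0 = female (reference), 1 = male.
    """
    if covariates is not None and sex_column in covariates.columns:
        raise ValueError("sex must not appear among the adjustment covariates")
    strata = strata or {"all": phenotypes.index}
    frames = []
    for name, ids in strata.items():
        ids = pd.Index(ids).intersection(phenotypes.index)
        if len(ids) == 0:
            warnings.warn(f"stratum {name!r} is empty, skipped")
            continue
        pheno = phenotypes.loc[ids].copy()
        pheno["_sex_group"] = np.where(pheno[sex_column].astype(int) == 1, "male", "female")
        res = group_compare(
            proteins,
            pheno,
            contrast=("female", "male"),
            group_column="_sex_group",
            covariates=covariates,
        )
        res["contrast"] = f"sex_{name}"
        frames.append(res)
    if not frames:
        return pd.DataFrame(columns=CONTRAST_COLUMNS)
    return pd.concat(frames, ignore_index=True)
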
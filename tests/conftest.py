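import numpy as np
import pandas as pd
import pytest

from proteopheno import design_demo_study, run_pipeline
from proteopheno.simulate import (
    PlantedEffect,
    SimulationConfig,
    simulate_genotypes,
    simulate_proteins,
)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full end-to-end demo study, shared by pipeline and acceptance tests."""
    outdir = tmp_path_factory.mktemp("demo")
    config = design_demo_study(seed=1)
    result = run_pipeline(config, outdir=outdir)
    result["outdir"] = outdir
    return result


@pytest.fixture(scope="session")
def small_study():
    """A small single-cohort study with one strong planted cis effect."""
    config = SimulationConfig(
        n_samples={"a": 1500},
        n_variants=60,
        block_sizes=[10] * 6,
        within_block_rho=0.8,
        maf_range=(0.2, 0.4),
        n_aptamers=8,
        planted_effects=[PlantedEffect("", "APT0001", 0.5, cis=True)],
        seed=7,
    )
    # resolve the placeholder variant id: plant on the 15th variant
    from proteopheno.simulate import _variant_table
    import dataclasses

    vid = _variant_table(config).index[15]
    config = dataclasses.replace(
        config, planted_effects=[PlantedEffect(vid, "APT0001", 0.5, cis=True)]
    )
    genotypes = simulate_genotypes(config)
    proteins, ledger, covariates = simulate_proteins(genotypes, config)
    return {
        "config": config,
        "variant": vid,
        "genotypes": genotypes,
        "proteins": proteins,
        "ledger": ledger,
        "covariates": covariates,
    }


def ols_oracle(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Explicit normal-equations least squares: betas and standard errors."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    return beta, se


def bh_stepup_bruteforce(pvals: np.ndarray, level: float = 0.05) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: reject all p <= the largest
    p_(i) with p_(i) <= i/m * level.  Returns a boolean rejection mask."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    thresh = level * (np.arange(1, m + 1)) / m
    passing = np.nonzero(pvals[order] <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if len(passing):
        reject[order[: passing.max() + 1]] = True
    return reject
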
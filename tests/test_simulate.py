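"""Statistical sanity of the synthetic-study generator: allele
frequencies, LD structure against the bivariate-normal oracle, planted
effect recovery, Hardy-Weinberg, disease GWAS behavior and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proteopheno.simulate import (
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

from conftest import ols_oracle


def _cfg(**kw):
    base = dict(
        n_samples={"a": 1000},
        n_variants=10,
        block_sizes=[10],
        within_block_rho=0.5,
        maf_range=(0.3, 0.3),
        n_aptamers=3,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_allele_frequency_matches_target(self):
        g = simulate_genotypes(_cfg(n_samples={"a": 10000}, n_variants=1, block_sizes=[1]))
        assert abs(g.allele_freq().iloc[0] - 0.3) < 0.02

    def test_independent_blocks_uncorrelated(self):
        g = simulate_genotypes(
            _cfg(n_samples={"a": 10000}, within_block_rho=0.0)
        )
        C = g.dosages.corr().to_numpy()
        off = np.abs(C[np.triu_indices(10, 1)])
        assert off.mean() < 0.05

    def test_adjacent_r2_matches_bivariate_normal_oracle(self):
        # closed-form oracle: allele correlation of two thresholded latent
        # Gaussians at correlation rho is the phi coefficient from the BVN CDF
        rho, maf = 0.95, 0.3
        z = stats.norm.ppf(maf)
        p11 = stats.multivariate_normal.cdf([z, z], mean=[0, 0], cov=[[1, rho], [rho, 1]])
        phi = (p11 - maf**2) / (maf * (1 - maf))
        g = simulate_genotypes(
            _cfg(n_samples={"a": 10000}, n_variants=2, block_sizes=[2], within_block_rho=rho)
        )
        r = g.dosages.corr().iloc[0, 1]
        assert r**2 == pytest.approx(phi**2, abs=0.04)
        assert r**2 > 0.55  # strong proxy structure is present

    def test_ld_decays_with_distance(self):
        g = simulate_genotypes(
            _cfg(n_samples={"a": 10000}, n_variants=6, block_sizes=[6], within_block_rho=0.9)
        )
        C = g.dosages.corr().to_numpy()
        lags = [np.mean([C[i, i + d] for i in range(6 - d)]) for d in (1, 2, 4)]
        assert lags[0] > lags[1] > lags[2] > 0

    def test_hardy_weinberg_consistency(self):
        g = simulate_genotypes(_cfg(n_samples={"a": 10000}, n_variants=40, block_sizes=[40]))
        ok = 0
        for vid in g.variant_ids:
            counts = g.dosages[vid].value_counts().reindex([0.0, 1.0, 2.0], fill_value=0)
            p = counts @ np.array([0, 1, 2]) / (2 * counts.sum())
            exp = counts.sum() * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            chi2 = ((counts.to_numpy() - exp) ** 2 / exp).sum()
            ok += stats.chi2.sf(chi2, 1) > 1e-4
        assert ok >= 0.95 * 40

    @pytest.mark.parametrize(
        "bad",
        [
            dict(maf_range=(0.0, 0.3)),
            dict(maf_range=(0.1, 0.6)),
            dict(block_sizes=[5]),
            dict(disease=DiseaseConfig(prevalence=0.0)),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            _cfg(**bad)

    def test_same_seed_identical_dosages(self):
        a = simulate_genotypes(_cfg())
        b = simulate_genotypes(_cfg())
        pd.testing.assert_frame_equal(a.dosages, b.dosages)


class TestProteins:
    def test_planted_effect_recovered_by_ols(self):
        cfg = _cfg(n_samples={"a": 5000}, noise_sd=1.0)
        vid = _variant_table(cfg).index[4]
        cfg = dataclasses.replace(cfg, planted_effects=[PlantedEffect(vid, "APT0001", 0.5)])
        g = simulate_genotypes(cfg)
        prot, ledger, _ = simulate_proteins(g, cfg)
        X = np.column_stack([np.ones(5000), g.dosages[vid].to_numpy()])
        beta, se = ols_oracle(prot.values["APT0001"].to_numpy(), X)
        assert beta[1] == pytest.approx(0.5, abs=0.05)
        assert ledger.lookup(vid, "APT0001") == 0.5

    def test_null_association_pvalues_uniform(self):
        cfg = _cfg(n_samples={"a": 500}, n_variants=40, block_sizes=[40],
                   within_block_rho=0.0, n_aptamers=10)
        g = simulate_genotypes(cfg)
        prot, _, _ = simulate_proteins(g, cfg)
        pvals = []
        for vid in g.variant_ids:
            x = g.dosages[vid].to_numpy()
            for apt in prot.aptamer_ids:
                r, p = stats.pearsonr(x, prot.values[apt].to_numpy())
                pvals.append(p)
        frac = np.mean(np.array(pvals) < 0.05)
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_unknown_aptamer_in_planted_effect_raises(self):
        cfg = _cfg()
        vid = _variant_table(cfg).index[0]
        cfg = dataclasses.replace(cfg, planted_effects=[PlantedEffect(vid, "NOPE", 0.5)])
        g = simulate_genotypes(cfg)
        with pytest.raises(KeyError, match="NOPE"):
            simulate_proteins(g, cfg)

    def test_injected_missingness_reaches_raw_export(self):
        cfg = _cfg(n_samples={"a": 400})
        g = simulate_genotypes(cfg)
        prot, _, cov = simulate_proteins(g, cfg)
        raw = export_raw(prot, cov, ArtifactPlan(missing_rate={"APT0002": 0.4}), seed=3)
        assert raw.values["APT0002"].isna().mean() == pytest.approx(0.4, abs=0.05)
        assert raw.values["APT0001"].notna().all()

    def test_covariate_effects_enter_protein(self):
        cfg = _cfg(n_samples={"a": 3000},
                   covariate_effects={"APT0001": {"sex": 0.8}})
        g = simulate_genotypes(cfg)
        prot, _, cov = simulate_proteins(g, cfg)
        diff = (
            prot.values.loc[cov["sex"] == 1, "APT0001"].mean()
            - prot.values.loc[cov["sex"] == 0, "APT0001"].mean()
        )
        assert diff == pytest.approx(0.8, abs=0.15)


class TestDiseaseGwas:
    def _disease_cfg(self, theta, n_gwas=4000):
        cfg = _cfg(n_variants=20, block_sizes=[20], within_block_rho=0.3)
        vid = _variant_table(cfg).index[10]
        return dataclasses.replace(
            cfg,
            planted_effects=[PlantedEffect(vid, "APT0001", 0.6, cis=True)],
            disease=DiseaseConfig(
                protein_mediation=(("APT0001", theta),), prevalence=0.2, n_gwas=n_gwas
            ),
        ), vid

    def test_null_gwas_pvalues_uniform(self):
        cfg, _ = self._disease_cfg(theta=0.0)
        g = simulate_genotypes(cfg)
        _, ledger, _ = simulate_proteins(g, cfg)
        gwas = simulate_disease_gwas(cfg, ledger)
        assert stats.kstest(gwas["P"], "uniform").pvalue > 0.01

    def test_mediated_snp_genome_wide_significant(self):
        # power oracle: per-allele liability effect theta*beta = 0.3, so the
        # non-centrality at n=20000 is far beyond the 5e-8 threshold
        cfg, vid = self._disease_cfg(theta=0.5, n_gwas=20000)
        ncp = 0.5 * 0.6 * np.sqrt(20000 * 2 * 0.3 * 0.7)
        assert ncp > stats.norm.isf(5e-8 / 2) + 3
        g = simulate_genotypes(cfg)
        _, ledger, _ = simulate_proteins(g, cfg)
        gwas = simulate_disease_gwas(cfg, ledger)
        assert gwas.set_index("SNP").loc[vid, "P"] < 5e-8

    def test_logistic_scale_agrees_in_direction(self):
        cfg, vid = self._disease_cfg(theta=0.5, n_gwas=3000)
        g = simulate_genotypes(cfg)
        _, ledger, _ = simulate_proteins(g, cfg)
        gwas = simulate_disease_gwas(cfg, ledger, scale="logistic")
        assert gwas.set_index("SNP").loc[vid, "BETA"] > 0

    def test_same_seed_byte_identical_files(self, tmp_path):
        from proteopheno.io import write_gwas_tsv

        cfg, _ = self._disease_cfg(theta=0.3, n_gwas=1000)
        g = simulate_genotypes(cfg)
        _, ledger, _ = simulate_proteins(g, cfg)
        paths = []
        for name in ("a.tsv", "b.tsv"):
            gwas = simulate_disease_gwas(cfg, ledger)
            write_gwas_tsv(gwas, tmp_path / name)
            paths.append((tmp_path / name).read_bytes())
        assert paths[0] == paths[1]

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            DiseaseConfig(prevalence=1.0), _cfg(disease=DiseaseConfig(prevalence=1.0))


class TestCellTypeExpression:
    CELLS = ["microglia", "astrocyte", "neuron", "oligodendrocyte", "endothelial"]

    def test_planned_dominance_recovered(self):
        from proteopheno.celltype import assign_specificity

        expr = simulate_celltype_expression(
            ["G1"], self.CELLS, {"G1": [0.6, 0.1, 0.1, 0.1, 0.1]}, seed=0
        )
        assert assign_specificity(expr).loc["G1", "call"] == "microglia"

    def test_exact_half_share_is_none(self):
        from proteopheno.celltype import assign_specificity

        expr = simulate_celltype_expression(
            ["G1"], self.CELLS, {"G1": [0.5, 0.2, 0.1, 0.1, 0.1]}, seed=0
        )
        assert assign_specificity(expr).loc["G1", "call"] == "none"

    def test_equal_shares_none(self):
        from proteopheno.celltype import assign_specificity

        expr = simulate_celltype_expression(["G1"], self.CELLS, {"G1": [0.2] * 5}, seed=0)
        assert assign_specificity(expr).loc["G1", "call"] == "none"

    def test_shares_not_summing_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_celltype_expression(["G1"], self.CELLS, {"G1": [0.5, 0.5, 0.5, 0, 0]})

    def test_unplanned_genes_stay_below_half(self):
        expr = simulate_celltype_expression(
            [f"G{i}" for i in range(20)], self.CELLS, {}, seed=4
        )
        shares = expr.div(expr.sum(axis=1), axis=0)
        assert (shares.max(axis=1) <= 0.5).all()
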
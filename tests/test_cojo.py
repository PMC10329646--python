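"""Conditional-joint selection: Benjamini-Hochberg against a brute-force
step-up, summary-statistic joint fits against individual-level multiple
regression, stepwise recovery of planted signals, LD pruning, and the
sentinel discovery loop on a forced design."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from proteopheno.cojo import (
    LdMatrix,
    conditional_stats,
    discovery_loop,
    ld_prune,
    phewas,
    stepwise_select,
)
from proteopheno.scan import linear_scan
from proteopheno.simulate import (
    PlantedEffect,
    SimulationConfig,
    _variant_table,
    simulate_genotypes,
    simulate_proteins,
)

from conftest import bh_stepup_bruteforce, ols_oracle


def _phewas_records(pvals: dict[str, float], vid="v") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": vid,
            "aptamer_id": list(pvals),
            "p": list(pvals.values()),
        }
    )


class TestPhewas:
    def test_hand_computed_bh(self):
        res = phewas("v", _phewas_records({"a1": 1e-10, "a2": 0.04, "a3": 0.9}))
        assert list(res["aptamer_id"]) == ["a1"]
        assert res["q"].iloc[0] == pytest.approx(3e-10)

    def test_all_ones_nothing_significant(self):
        res = phewas("v", _phewas_records({"a1": 1.0, "a2": 1.0}))
        assert res.empty

    def test_single_aptamer_identity(self):
        res = phewas("v", _phewas_records({"a1": 0.03}))
        assert len(res) == 1 and res["q"].iloc[0] == pytest.approx(0.03)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_bruteforce_stepup(self, pvals):
        pvals = np.array(pvals)
        recs = _phewas_records({f"a{i}": p for i, p in enumerate(pvals)})
        res = phewas("v", recs, fdr_level=0.05)
        expected = {f"a{i}" for i in np.nonzero(bh_stepup_bruteforce(pvals, 0.05))[0]}
        assert set(res["aptamer_id"]) == expected


def _cojo_study(seed=17, n=2000, n_variants=50, effects_at=(), betas=(), rho=0.6,
                maf=(0.15, 0.45)):
    cfg = SimulationConfig(
        n_samples={"a": n},
        n_variants=n_variants,
        block_sizes=[10] * (n_variants // 10),
        within_block_rho=rho,
        maf_range=maf,
        n_aptamers=1,
        seed=seed,
    )
    ids = _variant_table(cfg).index
    cfg = dataclasses.replace(
        cfg,
        planted_effects=[
            PlantedEffect(ids[i], "APT0001", b) for i, b in zip(effects_at, betas)
        ],
    )
    g = simulate_genotypes(cfg)
    prot, ledger, cov = simulate_proteins(g, cfg)
    assoc = linear_scan(g, prot, None, n_pcs=0, min_n=10)
    return g, prot, assoc, ids


class TestConditionalStats:
    def test_orthogonal_snps_conditional_equals_marginal(self):
        g, prot, assoc, ids = _cojo_study(effects_at=(5, 25), betas=(0.3, 0.3), rho=0.0)
        ld = LdMatrix.from_genotypes(g)
        cond = conditional_stats(assoc, ld, [ids[25]]).set_index("variant_id")
        marg = assoc.set_index("variant_id")
        # SNP 5 sits in an independent block: conditioning barely moves it
        assert cond.loc[ids[5], "beta_cond"] == pytest.approx(
            marg.loc[ids[5], "beta"], abs=3 * marg.loc[ids[5], "se"] * 0.2
        )

    def test_proxy_conditional_beta_near_zero(self):
        g, prot, assoc, ids = _cojo_study(
            effects_at=(5,), betas=(0.5,), rho=0.95, maf=(0.3, 0.3)
        )
        ld = LdMatrix.from_genotypes(g)
        proxy = ids[6]  # adjacent in the same block, r high
        assert ld.r.loc[ids[5], proxy] ** 2 > 0.5
        cond = conditional_stats(assoc, ld, [ids[5]]).set_index("variant_id")
        # oracle: joint multiple regression of protein on both SNPs
        X = np.column_stack(
            [np.ones(2000), g.dosages[ids[5]].to_numpy(), g.dosages[proxy].to_numpy()]
        )
        beta_oracle, se_oracle = ols_oracle(prot.values["APT0001"].to_numpy(), X)
        assert cond.loc[proxy, "beta_cond"] == pytest.approx(beta_oracle[2], abs=1e-6)
        assert cond.loc[proxy, "se_cond"] == pytest.approx(se_oracle[2], abs=1e-6)

    def test_conditioning_on_self_flagged(self):
        g, _, assoc, ids = _cojo_study(effects_at=(5,), betas=(0.4,))
        ld = LdMatrix.from_genotypes(g)
        cond = conditional_stats(assoc, ld, [ids[5]]).set_index("variant_id")
        assert cond.loc[ids[5], "flag"] == "self"
        assert cond.loc[ids[5], "beta_cond"] == 0.0

    def test_singular_ld_raises_naming_variants(self):
        g, _, assoc, ids = _cojo_study(effects_at=(5,), betas=(0.4,))
        g.dosages[ids[1]] = g.dosages[ids[0]]  # perfect duplicate
        ld = LdMatrix.from_genotypes(g)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            conditional_stats(
                assoc, ld, [ids[0], ids[1]], collinearity=1.01
            )


class TestStepwise:
    def test_joint_fit_matches_individual_level_regression(self):
        g, prot, assoc, ids = _cojo_study(effects_at=(5, 25), betas=(0.3, 0.25))
        ld = LdMatrix.from_genotypes(g)
        sel = stepwise_select(assoc, ld, p_entry=5e-8)
        assert set(sel.variant_ids) == {ids[5], ids[25]}
        X = np.column_stack(
            [np.ones(2000)] + [g.dosages[v].to_numpy() for v in sel.variant_ids]
        )
        beta_oracle, se_oracle = ols_oracle(prot.values["APT0001"].to_numpy(), X)
        joint = sel.selected.set_index("variant_id")
        for i, vid in enumerate(sel.variant_ids):
            assert joint.loc[vid, "beta_joint"] == pytest.approx(beta_oracle[i + 1], abs=1e-6)
            assert joint.loc[vid, "se_joint"] == pytest.approx(se_oracle[i + 1], abs=1e-6)

    def test_no_snp_below_entry_threshold_empty(self):
        g, _, assoc, _ = _cojo_study(effects_at=(), betas=())
        ld = LdMatrix.from_genotypes(g)
        sel = stepwise_select(assoc, ld, p_entry=5e-8)
        assert sel.variant_ids == []

    def test_correct_locus_recovery_rate(self):
        # two planted independent signals; the selected set must hit both
        # planted blocks (the causal SNP or an in-block proxy) and nothing else
        hits = 0
        reps = 30
        for rep in range(reps):
            g, _, assoc, ids = _cojo_study(
                seed=100 + rep, n=1500, effects_at=(5, 25), betas=(0.35, 0.3)
            )
            ld = LdMatrix.from_genotypes(g)
            sel = stepwise_select(assoc, ld, p_entry=5e-8)
            blocks = {ids.get_loc(v) // 10 for v in sel.variant_ids}
            hits += blocks == {0, 2}
        assert hits / reps >= 0.9

    def test_pure_proxy_never_coselected(self):
        for rep in range(20):
            g, _, assoc, ids = _cojo_study(
                seed=300 + rep, n=1500, effects_at=(5,), betas=(0.5,), rho=0.92
            )
            ld = LdMatrix.from_genotypes(g)
            sel = stepwise_select(assoc, ld, p_entry=5e-8)
            in_block = [v for v in sel.variant_ids if ids.get_loc(v) // 10 == 0]
            assert len(in_block) <= 1


def _toy_ld(r: np.ndarray, ids: list[str]) -> LdMatrix:
    return LdMatrix(
        r=pd.DataFrame(r, index=ids, columns=ids),
        sd=pd.Series(0.5, index=ids),
        n=1000,
    )


class TestLdPrune:
    def test_high_r2_pair_drops_one(self):
        ids = ["v1", "v2"]
        r = np.array([[1.0, np.sqrt(0.9)], [np.sqrt(0.9), 1.0]])
        tab = pd.DataFrame({"variant_id": ids, "p": [1e-10, 1e-6]})
        assert ld_prune(tab, _toy_ld(r, ids)) == ["v1"]

    def test_exact_boundary_pair_kept(self):
        ids = ["v1", "v2"]
        r = np.array([[1.0, np.sqrt(0.85)], [np.sqrt(0.85), 1.0]])
        tab = pd.DataFrame({"variant_id": ids, "p": [1e-10, 1e-6]})
        assert ld_prune(tab, _toy_ld(r, ids)) == ["v1", "v2"]

    def test_fifteen_to_twelve_fixture(self):
        # 15 variants, 3 proxy pairs at r2=0.9, everything else independent
        ids = [f"v{i:02d}" for i in range(15)]
        r = np.eye(15)
        for a, b in [(0, 1), (4, 5), (8, 9)]:
            r[a, b] = r[b, a] = np.sqrt(0.9)
        tab = pd.DataFrame({"variant_id": ids, "p": np.linspace(1e-12, 1e-4, 15)})
        kept = ld_prune(tab, _toy_ld(r, ids))
        assert len(kept) == 12
        # brute-force check: kept set is pairwise r2 <= 0.85 and maximal
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert r[ids.index(a), ids.index(b)] ** 2 <= 0.85
        for v in set(ids) - set(kept):
            assert any(r[ids.index(v), ids.index(k)] ** 2 > 0.85 for k in kept)


@pytest.fixture(scope="module")
def forced_design():
    """Sentinel hits aptamers 1-3, an independent SNP hits 3-5."""
    cfg = SimulationConfig(
        n_samples={"a": 2000},
        n_variants=100,
        block_sizes=[10] * 10,
        within_block_rho=0.7,
        maf_range=(0.2, 0.45),
        n_aptamers=12,
        seed=23,
    )
    ids = _variant_table(cfg).index
    sentinel, snp2 = ids[15], ids[65]
    cfg = dataclasses.replace(
        cfg,
        planted_effects=[
            PlantedEffect(sentinel, "APT0001", 0.5),
            PlantedEffect(sentinel, "APT0002", 0.5),
            PlantedEffect(sentinel, "APT0003", 0.45),
            PlantedEffect(snp2, "APT0003", 0.45),
            PlantedEffect(snp2, "APT0004", 0.5),
            PlantedEffect(snp2, "APT0005", 0.5),
        ],
    )
    g = simulate_genotypes(cfg)
    prot, _, cov = simulate_proteins(g, cfg)
    assoc = linear_scan(g, prot, None, n_pcs=0)
    return g, assoc, sentinel, snp2


class TestDiscoveryLoop:
    def test_recovers_planted_snps_and_aptamers(self, forced_design):
        g, assoc, sentinel, snp2 = forced_design
        ld = LdMatrix.from_genotypes(g)
        out = discovery_loop(sentinel, assoc, ld)
        assert set(out["variants"]) == {sentinel, snp2}
        assert out["aptamers"] == [f"APT{i:04d}" for i in range(1, 6)]

    def test_sentinel_without_signal_empty(self, forced_design):
        g, assoc, _, _ = forced_design
        ld = LdMatrix.from_genotypes(g)
        lonely = g.variant_ids[95]  # block with no planted effects
        out = discovery_loop(lonely, assoc, ld)
        assert out["aptamers"] == []

    def test_proxies_collapse_to_single_snp(self, forced_design):
        g, assoc, sentinel, snp2 = forced_design
        ld = LdMatrix.from_genotypes(g)
        out = discovery_loop(sentinel, assoc, ld)
        block_of = {v: g.variants.loc[v, "block"] for v in out["variants"]}
        assert len(set(block_of.values())) == len(out["variants"])
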
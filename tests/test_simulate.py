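"""Synthetic cohort generator: HWE, LD, planted effects, pooling, exomes."""

import math

import numpy as np
import pandas as pd
import pytest

from ibdarch import evaluate, simulate
from ibdarch.errors import EmptyGeneSetError, EmptyStratumError, UnknownSampleError, UnknownSiteError


class TestPanelAndCohort:
    def test_positions_strictly_increasing_and_block_structure(self, small_panel):
        assert small_panel.n_sites == 21
        assert (np.diff(small_panel.sites["pos"]) > 0).all()
        assert small_panel.sites["block_id"].nunique() == 2

    def test_bad_maf_rejected(self):
        with pytest.raises(ValueError, match="MAF"):
            simulate.build_panel([("b", 2, 100, 100)], mafs=np.array([0.3, 0.6]))

    def test_cohort_structure(self, screen_cohort):
        sizes = screen_cohort.groupby(["diagnosis", "onset"]).size()
        assert sizes[("CD", "pediatric")] == 356
        assert sizes[("UC", "adult")] == 260
        assert sizes[("HC", "not_applicable")] == 724
        hc = screen_cohort[screen_cohort["diagnosis"] == "HC"]
        assert (hc["onset"] == "not_applicable").all()
        assert hc["age_at_onset"].isna().all()
        ped = screen_cohort[screen_cohort["onset"] == "pediatric"]
        assert (ped["age_at_onset"] < 17).all()


class TestSimulateGenotypes:
    def test_controls_fit_hardy_weinberg(self):
        """At MAF 0.3 the genotype classes should match (0.49, 0.42, 0.09)."""
        rate = evaluate.hwe_goodness_of_fit_pass_rate(
            n_controls=10_000, n_sites=200, maf=0.3, seed=11
        )
        assert rate >= 0.99

    def test_null_effect_equalises_case_and_control_frequencies(self, small_panel):
        effects = simulate.EffectSpec.from_dict(
            {"site00003": {s: 1.0 for s in ("CD:pediatric", "CD:adult", "UC:pediatric", "UC:adult")}}
        )
        cohort = simulate.build_cohort(800, 0, 0, 0, 800, seed=5)
        gm = simulate.simulate_genotypes(small_panel, effects, cohort, 6)
        case = gm.allele_freq((gm.samples["diagnosis"] == "CD").to_numpy())
        ctrl = gm.allele_freq((gm.samples["diagnosis"] == "HC").to_numpy())
        assert np.abs(case - ctrl).max() < 0.05

    def test_planted_or_raises_case_allele_frequency(self, small_panel):
        effects = simulate.EffectSpec.from_dict({"site00000": {"CD:pediatric": 2.0}})
        cohort = simulate.build_cohort(4000, 0, 0, 0, 4000, seed=7)
        gm = simulate.simulate_genotypes(small_panel, effects, cohort, 8)
        case = gm.allele_freq((gm.samples["diagnosis"] == "CD").to_numpy())
        ctrl = gm.allele_freq((gm.samples["diagnosis"] == "HC").to_numpy())
        p = small_panel.sites["maf"].iloc[0]
        expected = 2.0 * p / (1 - p + 2.0 * p)
        assert case[0] == pytest.approx(expected, abs=0.02)
        assert case[0] > ctrl[0]

    def test_planted_logor_recovered_downstream(self):
        """Mean estimated log-OR across replicates recovers log 2.5."""
        rec = evaluate.allelic_logor_recovery(
            oratios=(2.5,), n_cases=1000, n_controls=1000, n_seeds=25, seed=3
        )
        assert abs(rec[2.5] - math.log(2.5)) < 0.1

    def test_ld_rho_induces_within_block_correlation(self):
        panel = simulate.build_panel(
            [("b", 10, 1000, 1000)], mafs=np.full(10, 0.4), ld_rho=0.9
        )
        cohort = simulate.build_cohort(0, 0, 0, 0, 2000, seed=1)
        gm = simulate.simulate_genotypes(panel, simulate.EffectSpec(), cohort, 2)
        r = np.corrcoef(gm.genotypes.T)
        off = r[np.triu_indices(10, 1)]
        assert off.mean() > 0.5  # strong LD between block members

    def test_unknown_effect_site_rejected(self, small_panel):
        effects = simulate.EffectSpec.from_dict({"nope": {"CD:adult": 2.0}})
        cohort = simulate.build_cohort(1, 1, 1, 1, 1)
        with pytest.raises(UnknownSiteError):
            simulate.simulate_genotypes(small_panel, effects, cohort, 0)

    def test_empty_cohort_rejected(self, small_panel):
        with pytest.raises(ValueError):
            simulate.simulate_genotypes(
                small_panel, simulate.EffectSpec(), simulate.build_cohort(0, 0, 0, 0, 0), 0
            )

    def test_same_seed_reproduces_bit_identical_genotypes(self, small_panel, screen_cohort):
        g1 = simulate.simulate_genotypes(small_panel, simulate.EffectSpec(), screen_cohort, 42)
        g2 = simulate.simulate_genotypes(small_panel, simulate.EffectSpec(), screen_cohort, 42)
        assert np.array_equal(g1.genotypes, g2.genotypes)


class TestBuildPools:
    def test_study_design_pool_counts(self, screen_cohort):
        pools = simulate.build_pools(screen_cohort, seed=9)
        per_stratum = pools.pools.groupby("stratum").size()
        assert per_stratum["UC:adult"] == 9
        assert per_stratum["UC:pediatric"] == 16
        assert per_stratum["CD:adult"] == 10
        assert per_stratum["CD:pediatric"] == 14
        assert per_stratum["HC:not_applicable"] == 30
        case = pools.pools[pools.pools["diagnosis"] != "HC"]
        assert len(case) == 49 and pools.n_pools == 79

    def test_each_sample_in_exactly_one_pool(self, screen_cohort):
        pools = simulate.build_pools(screen_cohort, seed=9)
        assert sorted(pools.membership["sample_id"]) == sorted(screen_cohort["sample_id"])
        assert pools.membership["sample_id"].is_unique
        merged = pools.membership.merge(pools.pools, on="pool_id")
        meta = screen_cohort.set_index("sample_id")
        strata = meta.loc[merged["sample_id"], "diagnosis"] + ":" + meta.loc[
            merged["sample_id"], "onset"]
        assert (strata.to_numpy() == merged["stratum"].to_numpy()).all()

    def test_single_pool_degenerate_partition(self):
        cohort = simulate.build_cohort(24, 0, 0, 0, 0, seed=1)
        pools = simulate.build_pools(cohort, {"CD:pediatric": {"pool_size": 24}})
        assert pools.n_pools == 1
        assert pools.pools["n_samples"].iloc[0] == 24

    @pytest.mark.parametrize(
        "remainder,expected",
        [("trailing", [30, 30, 30, 10]), ("absorb", [30, 30, 40])],
    )
    def test_remainder_policies(self, remainder, expected):
        cohort = simulate.build_cohort(100, 0, 0, 0, 0, seed=1)
        pools = simulate.build_pools(
            cohort, {"CD:pediatric": {"pool_size": 30}}, remainder=remainder, seed=2
        )
        assert sorted(pools.pools["n_samples"]) == sorted(expected)

    def test_empty_stratum_with_requested_pools_rejected(self):
        cohort = simulate.build_cohort(10, 0, 0, 0, 0, seed=1)
        with pytest.raises(EmptyStratumError):
            simulate.build_pools(cohort, {"UC:adult": {"n_pools": 2}})


class TestPoolIntensities:
    def _fixed_freq_matrix(self, freq=0.3, n_samples=10, n_sites=1000):
        """Genotype matrix whose every site has exactly the given pool frequency."""
        minor = int(round(freq * 2 * n_samples))
        col = np.zeros(n_samples, dtype=np.int8)
        full, rem = divmod(minor, 2)
        col[:full] = 2
        if rem:
            col[full] = 1
        geno = np.tile(col[:, None], (1, n_sites))
        cohort = simulate.build_cohort(n_samples, 0, 0, 0, 0, seed=0)
        sites = pd.DataFrame({
            "site_id": [f"x{i}" for i in range(n_sites)], "chrom": "1",
            "pos": np.arange(1, n_sites + 1), "block_id": "b", "maf": freq,
        })
        return simulate.GenotypeMatrix(geno, cohort, sites)

    def _one_pool(self, gm):
        return simulate.build_pools(
            gm.samples, {"CD:pediatric": {"pool_size": len(gm.samples)}}, seed=0
        )

    def test_monomorphic_pool_noiseless_fraction_is_exact(self):
        gm = self._fixed_freq_matrix(freq=1.0, n_sites=3)
        pi = simulate.simulate_pool_intensities(self._one_pool(gm), gm, noise_sd=0.0)
        assert np.allclose(pi.a / (pi.a + pi.b), 1.0)

    def test_half_frequency_unbiased_channel_symmetry(self):
        gm = self._fixed_freq_matrix(freq=0.5, n_sites=3)
        pi = simulate.simulate_pool_intensities(self._one_pool(gm), gm, noise_sd=0.0, k_bias=1.0)
        assert np.allclose(pi.a / (pi.a + pi.b), 0.5)

    def test_noisy_fraction_centers_on_true_frequency(self):
        gm = self._fixed_freq_matrix(freq=0.3, n_sites=1000)
        pi = simulate.simulate_pool_intensities(self._one_pool(gm), gm, noise_sd=0.02, seed=4)
        est = pi.a / (pi.a + pi.b)
        assert est.mean() == pytest.approx(0.30, abs=0.005)

    def test_pool_frequencies_conserve_genotype_margins(self, small_panel, screen_cohort):
        """Sample-weighted mean of noiseless pool frequencies equals the cohort
        allele frequency (margin conservation between matrix and pool views)."""
        gm = simulate.simulate_genotypes(small_panel, simulate.EffectSpec(), screen_cohort, 12)
        pools = simulate.build_pools(screen_cohort, seed=13)
        pi = simulate.simulate_pool_intensities(pools, gm, noise_sd=0.0)
        f = pi.a / (pi.a + pi.b)
        w = pools.pools["n_samples"].to_numpy(float)
        pooled = (f * w[:, None]).sum(axis=0) / w.sum()
        assert np.allclose(pooled, gm.allele_freq(), atol=1e-12)

    def test_unknown_pool_member_rejected(self, small_panel):
        cohort = simulate.build_cohort(4, 0, 0, 0, 0, seed=1)
        gm = simulate.simulate_genotypes(small_panel, simulate.EffectSpec(), cohort, 2)
        pools = simulate.build_pools(cohort, {"CD:pediatric": {"n_pools": 2}}, seed=3)
        pools.membership.loc[0, "sample_id"] = "ghost"
        with pytest.raises(UnknownSampleError):
            simulate.simulate_pool_intensities(pools, gm)


class TestSimulateExomes:
    def test_null_burden_centers_on_one(self):
        lor = evaluate.burden_logor_recovery(planted_or=1.0, n_seeds=40, seed=21)
        assert abs(lor) < 0.05

    def test_zero_variant_rate_gives_empty_table(self):
        spec = simulate.ExomeSimSpec(
            gene_sets={"S": ["g1", "g2"]}, variants_per_gene=0.0
        )
        table = simulate.simulate_exomes(spec, 1)
        assert len(table.variants) == 0
        assert table.genotypes.shape == (0, sum(spec.group_sizes.values()))

    def test_empty_gene_set_rejected(self):
        with pytest.raises(EmptyGeneSetError):
            simulate.simulate_exomes(simulate.ExomeSimSpec(gene_sets={"S": []}), 1)

    def test_novel_variants_have_no_panel_mafs(self):
        spec = simulate.ExomeSimSpec(gene_sets=simulate.default_gene_sets(20))
        table = simulate.simulate_exomes(spec, 5)
        novel = table.variants[table.variants["novel"]]
        assert len(novel) > 0
        assert novel[["maf_1kgp", "maf_esp", "maf_exac"]].isna().all().all()
        known = table.variants[~table.variants["novel"]]
        assert (known[["maf_1kgp", "maf_esp", "maf_exac"]] < 0.02).all().all()

    def test_group_sizes_and_determinism(self):
        spec = simulate.ExomeSimSpec(gene_sets=simulate.default_gene_sets(20))
        t1 = simulate.simulate_exomes(spec, 9)
        t2 = simulate.simulate_exomes(spec, 9)
        assert t1.samples.groupby("group").size().to_dict() == {
            "Adult-CD": 23, "Adult-UC": 22, "HC": 18, "VEO-CD": 21, "VEO-UC": 22,
        }
        assert np.array_equal(t1.genotypes, t2.genotypes)
        pd.testing.assert_frame_equal(t1.variants, t2.variants)
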
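"""Pooled-screen: frequency estimation, per-SNP test, nine comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from ibdarch import evaluate, screen, simulate
from ibdarch.errors import TooFewPoolsError


class TestEstimatePoolFreq:
    @pytest.mark.parametrize("a,b,k,expected", [(2.0, 0.0, 1.0, 1.0), (1.0, 1.0, 1.0, 0.5)])
    def test_boundary_and_symmetry(self, a, b, k, expected):
        assert screen.estimate_pool_freq(a, b, k) == expected

    def test_zero_total_intensity_is_missing(self):
        f = screen.estimate_pool_freq(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isnan(f[0]) and f[1] == 0.5

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1e-6, 10), st.floats(1e-6, 10))
    def test_channel_swap_maps_f_to_one_minus_f(self, a, b):
        f = screen.estimate_pool_freq(a, b, 1.0)
        g = screen.estimate_pool_freq(b, a, 1.0)
        assert f + g == pytest.approx(1.0, abs=1e-9)

    def test_k_correction_inverts_generating_bias(self):
        # generated with k_bias=2: raw fraction is distorted, corrected is not
        a, b = 0.3, (1 - 0.3) / 2.0
        assert screen.estimate_pool_freq(a, b, 2.0) == pytest.approx(0.3)
        assert screen.estimate_pool_freq(a, b, 1.0) != pytest.approx(0.3)

    def test_estimator_centers_on_true_pooled_frequency(self):
        """Pools of 50 at true frequency 0.30, array noise 0.02: mean estimate
        within 0.01 of the true pooled allele count / 2N."""
        rng = np.random.default_rng(5)
        n, reps = 50, 1000
        dosages = rng.binomial(2, 0.30, size=(reps, n))
        true_f = dosages.sum(axis=1) / (2 * n)
        noisy = np.clip(true_f + rng.normal(0, 0.02, reps), 0, 1)
        est = screen.estimate_pool_freq(noisy, 1.0 - noisy, 1.0)
        assert est.mean() == pytest.approx(0.30, abs=0.01)


class TestPooledAssociationTest:
    def test_identical_arms_give_null(self):
        f = np.full(5, 0.30)
        t, p, d = screen.pooled_association_test(f, np.full(5, 24), f, np.full(5, 24))
        assert (t, p, d) == (0.0, 1.0, "0")

    def test_too_few_pools_rejected(self):
        with pytest.raises(TooFewPoolsError):
            screen.pooled_association_test([0.3], [24], [0.3, 0.31], [24, 24])

    def test_nan_pools_dropped_before_testing(self):
        case = np.array([0.3, np.nan, 0.32, 0.29])
        ctrl = np.array([0.30, 0.31, 0.29])
        t, p, d = screen.pooled_association_test(case, np.full(4, 24), ctrl, np.full(3, 24))
        assert np.isfinite(t) and 0 < p <= 1

    def test_planted_effect_yields_smaller_p_than_null(self):
        """Paired simulation: same seeds, OR 2.5 vs OR 1.0 at MAF 0.25."""
        p_eff, p_null = [], []
        for s in range(30):
            rng = np.random.default_rng(1000 + s)
            ctrl = rng.binomial(2 * 24, 0.25, size=30) / (2 * 24)
            p_case_eff = 2.5 * 0.25 / (1 - 0.25 + 2.5 * 0.25)
            for target, p_arm in ((p_eff, p_case_eff), (p_null, 0.25)):
                case = rng.binomial(2 * 24, p_arm, size=49) / (2 * 24)
                target.append(
                    screen.pooled_association_test(case, np.full(49, 24), ctrl, np.full(30, 24))[1]
                )
        assert np.median(p_eff) < np.median(p_null)

    def test_null_pvalues_uniform(self):
        """KS test of screen P-values against U(0,1) under the global null."""
        rate, _ = evaluate.pooled_null_type1(n_sites=2000, seed=77)
        assert 0.03 <= rate <= 0.07
        # uniformity beyond the 0.05 tail: rebuild the null P distribution
        pvals = _null_screen_pvalues(seed=78, n_sites=1000)
        assert kstest(pvals, "uniform").pvalue > 0.001


def _null_screen_pvalues(seed: int, n_sites: int) -> np.ndarray:
    panel = simulate.build_panel(
        [(f"b{i}", 10, 2000, 50_000) for i in range(n_sites // 10)], ld_rho=0.0, seed=seed
    )
    cohort = simulate.default_screen_cohort(seed=seed + 1)
    gm = simulate.simulate_genotypes(panel, simulate.EffectSpec(), cohort, seed + 2)
    pools = simulate.build_pools(cohort, seed=seed + 3)
    pi = simulate.simulate_pool_intensities(pools, gm, seed=seed + 4)
    freqs = screen.estimate_pool_frequencies(pi)
    comp = [c for c in screen.nine_comparisons() if c.label == "IBD:all"]
    return screen.run_screen(freqs, pools, comp)["p"].to_numpy()


@pytest.fixture(scope="module")
def screen_setup():
    panel = simulate.build_panel(
        [(f"b{i}", 10, 2000, 50_000) for i in range(10)], ld_rho=0.0, seed=51
    )
    cohort = simulate.build_cohort(120, 80, 100, 90, 200, seed=52)
    effects = simulate.EffectSpec.from_dict({"site00000": {"CD:pediatric": 3.0}})
    gm = simulate.simulate_genotypes(panel, effects, cohort, 53)
    pools = simulate.build_pools(
        cohort,
        {s: {"n_pools": 4} for s in
         ("CD:pediatric", "CD:adult", "UC:pediatric", "UC:adult")}
        | {"HC:not_applicable": {"n_pools": 8}},
        seed=54,
    )
    pi = simulate.simulate_pool_intensities(pools, gm, seed=55)
    freqs = screen.estimate_pool_frequencies(pi)
    return freqs, pools


class TestRunScreen:

    def test_cardinality_sites_times_nine_comparisons(self, screen_setup):
        freqs, pools = screen_setup
        res = screen.run_screen(freqs, pools)
        assert len(res) == 100 * 9
        assert set(res["comparison"]) == {c.label for c in screen.nine_comparisons()}
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()
        assert set(res["direction"]) <= {"+", "-", "0"}

    def test_vectorised_screen_matches_scalar_test(self, screen_setup):
        freqs, pools = screen_setup
        res = screen.run_screen(freqs, pools)
        meta = pools.pools.set_index("pool_id").loc[freqs.index]
        comp = screen.nine_comparisons()[0]  # IBD:all
        case = comp.case_pool_mask(meta)
        ctrl = comp.control_pool_mask(meta)
        for site in ["site00000", "site00042", "site00099"]:
            t, p, d = screen.pooled_association_test(
                freqs.loc[case, site], meta.loc[case, "n_samples"],
                freqs.loc[ctrl, site], meta.loc[ctrl, "n_samples"],
            )
            row = res[(res["site_id"] == site) & (res["comparison"] == "IBD:all")].iloc[0]
            assert row["stat"] == pytest.approx(t, rel=1e-9)
            assert row["p"] == pytest.approx(p, rel=1e-9)
            assert row["direction"] == d

    def test_comparison_without_case_pools_rejected(self, screen_setup):
        freqs, pools = screen_setup
        bogus = screen.Comparison("XX:all", ("XX",), ("pediatric", "adult"))
        with pytest.raises(TooFewPoolsError):
            screen.run_screen(freqs, pools, [bogus])

    def test_stratum_specific_effect_strongest_in_matching_comparison(self):
        """A pediatric-only planted effect should usually give a smaller P in
        the pediatric comparison than the adult one."""
        wins = 0
        n_seeds = 20
        panel = simulate.build_panel([("b", 1, 1000, 1000)], mafs=np.array([0.3]))
        effects = simulate.EffectSpec.from_dict(
            {"site00000": {"CD:pediatric": 2.5, "UC:pediatric": 2.5}}
        )
        for s in range(n_seeds):
            cohort = simulate.default_screen_cohort(seed=9000 + s)
            gm = simulate.simulate_genotypes(panel, effects, cohort, 9100 + s)
            pools = simulate.build_pools(cohort, seed=9200 + s)
            pi = simulate.simulate_pool_intensities(pools, gm, seed=9300 + s)
            res = screen.run_screen(screen.estimate_pool_frequencies(pi), pools)
            p_ped = res[res["comparison"] == "IBD:pediatric"]["p"].iloc[0]
            p_adu = res[res["comparison"] == "IBD:adult"]["p"].iloc[0]
            wins += int(p_ped < p_adu)
        assert wins >= 0.8 * n_seeds

    def test_permuting_pool_labels_destroys_association(self):
        """Shuffling pools between arms must break a strong planted signal."""
        panel = simulate.build_panel([("b", 1, 1000, 1000)], mafs=np.array([0.3]))
        effects = simulate.EffectSpec.from_dict(
            {"site00000": {s: 2.5 for s in
                           ("CD:pediatric", "CD:adult", "UC:pediatric", "UC:adult")}}
        )
        cohort = simulate.default_screen_cohort(seed=61)
        gm = simulate.simulate_genotypes(panel, effects, cohort, 62)
        pools = simulate.build_pools(cohort, seed=63)
        pi = simulate.simulate_pool_intensities(pools, gm, seed=64)
        freqs = screen.estimate_pool_frequencies(pi)
        meta = pools.pools.set_index("pool_id").loc[freqs.index]
        comp = screen.nine_comparisons()[0]
        case = comp.case_pool_mask(meta)
        w = meta["n_samples"].to_numpy(float)
        f = freqs["site00000"].to_numpy()
        p_true = screen.pooled_association_test(f[case], w[case], f[~case], w[~case])[1]
        rng = np.random.default_rng(65)
        p_perm = []
        for _ in range(99):
            perm = rng.permutation(len(f))
            c = case[perm]
            p_perm.append(screen.pooled_association_test(f[c], w[c], f[~c], w[~c])[1])
        assert p_true < 1e-6
        assert np.median(p_perm) > 0.05
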
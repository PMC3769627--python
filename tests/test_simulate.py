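"""Birth-death simulator: process law, conditioning, sampling, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from cladediv import (
    BDBackground,
    BDSimConfig,
    bd_aux,
    check_ultrametric,
    crown_size_cdf,
    mc_clade_size_quantiles,
    mc_crown_sizes,
    rates_from_background,
    simulate_bd,
    subsample_tips,
    write_newick,
)


class TestConfig:
    def test_lambda_mu_round_trip(self):
        lam, mu = rates_from_background(0.195, 0.9)
        assert lam - mu == pytest.approx(0.195, rel=1e-14)
        assert mu / lam == pytest.approx(0.9, rel=1e-14)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lambda_rate=0.0, t_stop=1.0),
            dict(lambda_rate=1.0, mu_rate=1.0, t_stop=1.0),
            dict(lambda_rate=1.0),  # neither stop rule
            dict(lambda_rate=1.0, t_stop=1.0, n_stop=5),  # both stop rules
            dict(lambda_rate=1.0, mu_rate=0.5, n_stop=5),  # n_stop with extinction
            dict(lambda_rate=1.0, t_stop=1.0, sampling_fraction=0.0),
            dict(lambda_rate=1.0, t_stop=1.0, condition="crown_both_survive",
                 start_mode="single_lineage"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BDSimConfig(**kwargs)


class TestSimulateBD:
    def test_vanishing_duration_keeps_crown_pair(self):
        for seed in range(20):
            res = simulate_bd(
                BDSimConfig(lambda_rate=1.0, t_stop=1e-4, seed=seed,
                            condition="crown_both_survive")
            )
            assert res.n_extant == 2

    def test_deterministic_for_fixed_seed(self):
        cfg = BDSimConfig(lambda_rate=1.0, mu_rate=0.3, t_stop=4.0,
                          condition="crown_both_survive", seed=42)
        a, b = simulate_bd(cfg), simulate_bd(cfg)
        assert write_newick(a.tree) == write_newick(b.tree)
        assert a.true_node_ages == b.true_node_ages

    def test_trees_validate_as_chronograms(self):
        for seed in range(10):
            res = simulate_bd(
                BDSimConfig(lambda_rate=0.9, mu_rate=0.4, t_stop=5.0,
                            condition="crown_both_survive", seed=seed)
            )
            assert res.n_extant == res.tree.tip_count
            assert check_ultrametric(res.tree, rel_tol=1e-9).passed

    def test_n_stop_reaches_target_tip_count(self):
        res = simulate_bd(
            BDSimConfig(lambda_rate=1.0, n_stop=12, start_mode="single_lineage", seed=3)
        )
        assert res.n_extant == 12
        assert check_ultrametric(res.tree, rel_tol=1e-9).passed

    def test_unconditioned_run_may_go_extinct(self):
        # high extinction, long time: some seeds die out and are flagged
        hit = False
        for seed in range(40):
            res = simulate_bd(
                BDSimConfig(lambda_rate=0.5, mu_rate=0.45, t_stop=20.0,
                            start_mode="single_lineage", seed=seed)
            )
            if res.degenerate:
                assert res.tree is None
                hit = True
        assert hit

    def test_rejection_cap_reports_acceptance(self):
        cfg = BDSimConfig(lambda_rate=0.5, mu_rate=0.45, t_stop=50.0,
                          condition="crown_both_survive", seed=0, max_attempts=3)
        with pytest.raises(Exception, match="attempts"):
            simulate_bd(cfg)

    def test_pure_birth_single_lineage_size_law(self):
        """Extant counts follow the geometric law P(n) = (1-β)β^{n-1}."""
        lam, t = 0.4, 5.0
        b = bd_aux(BDBackground(r=lam, epsilon=0.0), t).beta
        sizes = []
        for s in np.random.SeedSequence(2024).generate_state(2000) % (2 ** 31):
            res = simulate_bd(
                BDSimConfig(lambda_rate=lam, t_stop=t,
                            start_mode="single_lineage", seed=int(s))
            )
            sizes.append(res.n_extant)
        sizes = np.asarray(sizes)
        # chi-square against the geometric pmf, tail pooled
        kmax = 25
        expected = np.array(
            [(1 - b) * b ** (n - 1) for n in range(1, kmax)] + [b ** (kmax - 1)]
        ) * len(sizes)
        observed = np.array(
            [np.sum(sizes == n) for n in range(1, kmax)] + [np.sum(sizes >= kmax)]
        )
        keep = expected >= 5
        stat = np.sum((observed[keep] - expected[keep]) ** 2 / expected[keep])
        crit = stats.chi2.ppf(0.99, df=keep.sum() - 1)
        assert stat < crit


@pytest.fixture(scope="module")
def big_tree():
    return simulate_bd(
        BDSimConfig(lambda_rate=1.0, n_stop=1000,
                    start_mode="single_lineage", seed=11)
    )


class TestSubsampling:
    def test_rho_one_is_identity(self, big_tree):
        sub = subsample_tips(big_tree, 1.0, seed=5)
        assert sub.n_extant == big_tree.n_extant

    def test_retained_count_is_binomial(self, big_tree):
        kept = subsample_tips(big_tree, 0.5, seed=5).n_extant
        # 4 sigma band around Binomial(1000, 0.5)
        assert abs(kept - 500) < 4 * math.sqrt(1000 * 0.25)

    def test_pruning_preserves_ultrametricity_and_shrinks_crown(self, big_tree):
        orig_crown = max(big_tree.true_node_ages.values())
        for seed in range(5):
            sub = subsample_tips(big_tree, 0.3, seed=seed)
            assert check_ultrametric(sub.tree, rel_tol=1e-9).passed
            assert max(sub.true_node_ages.values()) <= orig_crown + 1e-12

    def test_degenerate_flag_when_too_few_tips_survive(self):
        small = simulate_bd(
            BDSimConfig(lambda_rate=1.0, t_stop=1e-4, seed=1,
                        condition="crown_both_survive")
        )
        sub = subsample_tips(small, 1e-6, seed=2)
        assert sub.degenerate and sub.tree is None

    def test_invalid_rho_rejected(self, big_tree):
        with pytest.raises(ValueError):
            subsample_tips(big_tree, 0.0, seed=1)


class TestMonteCarloOracle:
    def test_fixed_seed_is_bit_identical(self):
        a = mc_clade_size_quantiles(0.3, 0.5, 4.0, reps=20000, seed=9)
        b = mc_clade_size_quantiles(0.3, 0.5, 4.0, reps=20000, seed=9)
        assert a == b

    def test_crown_mean_matches_two_geometric_sum(self):
        """E[N] for a crown clade is 2/(1-β)."""
        r, eps, t = 0.5, 0.9, 4.0
        b = bd_aux(BDBackground(r=r, epsilon=eps), t).beta
        sizes = mc_crown_sizes(r, eps, t, reps=40000, seed=31)
        exact_mean = 2.0 / (1.0 - b)
        se = sizes.std() / math.sqrt(len(sizes))
        assert abs(sizes.mean() - exact_mean) < 4 * se

    def test_empirical_cdf_matches_closed_form(self):
        r, eps, t = 0.5, 0.9, 4.0
        bg = BDBackground(r=r, epsilon=eps)
        sizes = mc_crown_sizes(r, eps, t, reps=40000, seed=13)
        for n in (2, 5, 10, 30, 80):
            p = crown_size_cdf(n, bg, t)
            emp = np.mean(sizes <= n)
            tol = 4 * math.sqrt(p * (1 - p) / len(sizes)) + 1e-9
            assert abs(emp - p) < tol, n

    def test_higher_extinction_inflates_upper_quantile(self):
        lo = mc_clade_size_quantiles(0.195, 0.0, 9.79, reps=30000, seed=7)
        hi = mc_clade_size_quantiles(0.195, 0.9, 9.79, reps=30000, seed=7)
        assert hi.upper > lo.upper

    def test_tree_simulator_and_count_kernel_agree(self):
        """Full tree simulation and the count-level kernel are the same
        process: two-sample comparison of crown clade sizes."""
        r, eps, t = 0.4, 0.5, 3.0
        lam, mu = rates_from_background(r, eps)
        tree_sizes = []
        for s in np.random.SeedSequence(55).generate_state(800) % (2 ** 31):
            res = simulate_bd(
                BDSimConfig(lambda_rate=lam, mu_rate=mu, t_stop=t,
                            condition="crown_both_survive", seed=int(s))
            )
            tree_sizes.append(res.n_extant)
        kernel_sizes = mc_crown_sizes(r, eps, t, reps=20000, seed=56)
        stat = stats.ks_2samp(tree_sizes, kernel_sizes)
        assert stat.pvalue > 0.01
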
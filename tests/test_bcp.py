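import numpy as np
import pytest

from vishotspot import (
    BCPConfig,
    ThresholdSpec,
    bcp_fit,
    bcp_hotbins,
    check_convergence,
    select_method,
)

from .oracles import bcp_enumeration

FAST = BCPConfig(iterations=800, burnin=50, seed=4)


@pytest.fixture(scope="module")
def step_signal():
    rng = np.random.default_rng(12)
    x = rng.normal(0.0, 1.0, 60)
    x[25:35] += 8.0
    return x


class TestSamplerContracts:
    def test_same_seed_bit_identical(self, step_signal):
        a = bcp_fit(step_signal, FAST)
        b = bcp_fit(step_signal, FAST)
        assert np.array_equal(a.posterior_means, b.posterior_means)
        assert np.array_equal(a.change_probs, b.change_probs)

    def test_different_seeds_differ(self, step_signal):
        from dataclasses import replace

        a = bcp_fit(step_signal, FAST)
        b = bcp_fit(step_signal, replace(FAST, seed=5))
        assert not np.array_equal(a.change_probs, b.change_probs)

    def test_posterior_means_shrink_within_data_range(self, step_signal):
        r = bcp_fit(step_signal, FAST)
        assert r.posterior_means.min() >= step_signal.min() - 1e-9
        assert r.posterior_means.max() <= step_signal.max() + 1e-9

    def test_change_probs_are_probabilities(self, step_signal):
        r = bcp_fit(step_signal, FAST)
        assert len(r.change_probs) == len(step_signal) - 1
        assert ((r.change_probs >= 0) & (r.change_probs <= 1)).all()

    def test_constant_input_stays_single_block(self):
        x = np.full(30, 2.5)
        r = bcp_fit(x, FAST)
        np.testing.assert_allclose(r.posterior_means, 2.5)
        assert not bcp_hotbins(r, ThresholdSpec(2.6)).size

    def test_p0_to_zero_degenerates_to_grand_mean(self):
        # mild signal on a small instance: as p0 -> 0 the partition prior
        # overwhelms the likelihood and a single block remains
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 20)
        x[10:] += 2.0
        r = bcp_fit(x, BCPConfig(iterations=200, p0=1e-9, seed=0))
        np.testing.assert_allclose(r.posterior_means, x.mean(), rtol=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            bcp_fit(np.array([1.0, 2.0]), FAST)
        with pytest.raises(ValueError, match="non-finite"):
            bcp_fit(np.array([1.0, np.nan, 2.0]), FAST)
        with pytest.raises(ValueError):
            BCPConfig(iterations=0)
        with pytest.raises(ValueError):
            BCPConfig(p0=1.5)


class TestExactOracle:
    """Gibbs averages agree with full partition enumeration on short signals."""

    @pytest.mark.parametrize(
        "signal",
        [
            [0.3, -0.2, 0.1, 4.8, 5.2, 5.1, -0.3, 0.2, 0.0, -0.1],
            [1.0, 1.2, 0.8, 1.1, 0.9, 1.05, 1.15, 0.95],
            [0.0, 0.1, -0.1, 2.0, 2.1, 1.9, 4.0, 4.2, 3.9, 0.1, 0.0, -0.2],
        ],
        ids=["one-step", "no-signal", "two-steps"],
    )
    def test_matches_enumeration_within_monte_carlo_error(self, signal):
        x = np.asarray(signal)
        mu_exact, p_exact = bcp_enumeration(x)
        n_seeds = 12
        mus, ps = [], []
        for s in range(n_seeds):
            r = bcp_fit(x, BCPConfig(iterations=4_000, burnin=50, seed=s))
            mus.append(r.posterior_means)
            ps.append(r.change_probs)
        mus, ps = np.vstack(mus), np.vstack(ps)
        for est, exact in ((mus, mu_exact), (ps, p_exact)):
            mean = est.mean(axis=0)
            se = est.std(axis=0, ddof=1) / np.sqrt(n_seeds)
            assert (np.abs(mean - exact) <= 3 * np.maximum(se, 1e-4)).all()


class TestStepRecovery:
    def test_planted_step_bins_are_recovered(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0.0, 1.0, 400)
        z[200:205] = 500.0 + rng.normal(0.0, 1.0, 5)
        r = bcp_fit(z, BCPConfig(iterations=2_000, burnin=50, seed=1))
        hot = bcp_hotbins(r, ThresholdSpec(422.0))
        assert hot.tolist() == [200, 201, 202, 203, 204]
        assert np.delete(r.posterior_means, hot).max() < 50.0
        # change probability peaks exactly at the two step boundaries
        top2 = np.argsort(r.change_probs)[-2:]
        assert sorted(top2.tolist()) == [199, 204]


class TestConvergence:
    def test_constant_input_zero_range_across_seeds(self):
        rep = check_convergence(
            np.full(20, 1.0), BCPConfig(iterations=100, seed=0), n_seeds=3
        )
        assert rep.mu_range.max() == 0.0
        assert rep.consistent

    def test_planted_step_consistent_across_five_seeds(self, step_signal):
        rep = check_convergence(
            step_signal * 100.0,  # lift the step above the default threshold
            BCPConfig(iterations=5_000, seed=2),
            n_seeds=5,
        )
        assert rep.consistent
        assert not rep.recommend_more_iterations

    def test_short_runs_wobble_more_on_low_signal_bins(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 80)
        x[40:46] += 6.0
        rep = check_convergence(
            x, BCPConfig(iterations=150, seed=0), n_seeds=5,
            threshold=ThresholdSpec(3.0),
        )
        hot = x > 3.0
        assert rep.mu_range[~hot].max() >= rep.mu_range[hot].mean()


class TestBoundaryQC:
    def test_density_jump_at_chromosome_join_is_flagged(self):
        """Two chromosomes with very different mean z: the join boundary
        carries a high change probability and is reported; a uniform
        genome reports nothing."""
        from vishotspot import (
            BinProfile, ChromSizes, chromosome_boundary_changes,
            partition_genome,
        )

        g = ChromSizes((("chrA", 20_000_000), ("chrB", 20_000_000)))
        gp = partition_genome(g)
        rng = np.random.default_rng(1)
        z = np.concatenate(
            [rng.normal(0, 0.3, 20), rng.normal(30, 0.3, 20)]
        )
        res = bcp_fit(z, BCPConfig(iterations=500, seed=0))
        flagged = chromosome_boundary_changes(res, gp)
        assert [(f[1], f[2]) for f in flagged] == [("chrA", "chrB")]
        assert flagged[0][0] == 19 and flagged[0][3] > 0.9

        flat = bcp_fit(
            rng.normal(0, 0.3, 40), BCPConfig(iterations=500, seed=0)
        )
        assert chromosome_boundary_changes(flat, gp) == []


class TestSelectMethod:
    @pytest.mark.parametrize(
        "n,score,expected",
        [
            (922, 1 - 0.064, "bcp"),
            (250, 0.95, "zthreshold"),
            (384, 0.999, "zthreshold"),
            (300, 0.9, "bcp"),
        ],
    )
    def test_routing_rules(self, n, score, expected):
        assert select_method(n, score) == expected

    def test_tiny_datasets_refused(self):
        with pytest.raises(ValueError, match="too small"):
            select_method(100, 0.9)
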
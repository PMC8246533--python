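"""Mixed-logit simulated likelihood: oracles, invariances, recovery."""

import numpy as np
import pandas as pd
import pytest

import bwskit as bk
from bwskit import datasets
from bwskit.maxdiff import pair_probabilities
from bwskit.mixed import MixedMaxDiffModel, make_halton_draws, simulated_loglik


@pytest.fixture(scope="module")
def tiny_panel(design99):
    """N=3 respondents, first 2 cards only (incomplete on purpose)."""
    rows = []
    rng = np.random.default_rng(10)
    for n in range(3):
        for card_id in (0, 1):
            blk = sorted(design99.blocks[card_id])
            best, worst = rng.choice(blk, size=2, replace=False)
            rows.append((f"R{n}", card_id, int(best), int(worst)))
    return bk.ResponsePanel(design99, pd.DataFrame(
        rows, columns=["respondent_id", "card_id", "best", "worst"]),
        allow_incomplete=True)


class TestSimulatedLoglik:
    def test_zero_sigma_equals_pooled_exactly(self, small_panel):
        panel, _ = small_panel
        arrays = panel.to_arrays()
        rng = np.random.default_rng(3)
        mu = rng.normal(size=9)
        mu[8] = 0.0
        draws = rng.standard_normal((panel.n_respondents, 7, 9))
        from bwskit.maxdiff import loglik_pooled
        ll_sim = simulated_loglik(mu, np.zeros(9), arrays, draws)
        assert ll_sim == pytest.approx(loglik_pooled(mu, arrays), abs=1e-10)

    def test_single_zero_draw_equals_pooled(self, small_panel):
        panel, _ = small_panel
        arrays = panel.to_arrays()
        mu = np.linspace(-1, 1, 9)
        draws = np.zeros((panel.n_respondents, 1, 9))
        from bwskit.maxdiff import loglik_pooled
        sig = np.full(9, 2.0)
        assert simulated_loglik(mu, sig, arrays, draws) == pytest.approx(
            loglik_pooled(mu, arrays), abs=1e-10)

    def test_matches_hand_expanded_sum_of_products(self, tiny_panel):
        """Brute-force oracle: expand sum over draws of card-probability products."""
        rng = np.random.default_rng(7)
        mu = rng.normal(size=9)
        sigma = rng.uniform(0.2, 1.0, size=9)
        draws = rng.standard_normal((3, 2, 9))
        ll = simulated_loglik(mu, sigma, tiny_panel, draws)
        # independent expansion via pair_probabilities
        expected = 0.0
        frame = tiny_panel.frame
        for n, rid in enumerate(sorted(frame["respondent_id"].unique())):
            sub = frame[frame["respondent_id"] == rid]
            like = 0.0
            for r in range(2):
                beta = mu + np.abs(sigma) * draws[n, r]
                prod = 1.0
                for row in sub.itertuples(index=False):
                    blk = tiny_panel.design.blocks[row.card_id]
                    prod *= pair_probabilities(beta, blk)[(row.best, row.worst)]
                like += prod / 2.0
            expected += np.log(like)
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_permuting_draws_within_respondent(self, tiny_panel):
        rng = np.random.default_rng(8)
        mu = rng.normal(size=9)
        sigma = rng.uniform(0.1, 1.5, size=9)
        draws = rng.standard_normal((3, 6, 9))
        ll1 = simulated_loglik(mu, sigma, tiny_panel, draws)
        perm = draws[:, rng.permutation(6), :]
        ll2 = simulated_loglik(mu, sigma, tiny_panel, perm)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_zero_draw_count_rejected(self, tiny_panel):
        with pytest.raises(ValueError):
            simulated_loglik(np.zeros(9), np.zeros(9), tiny_panel,
                             np.zeros((3, 0, 9)))


class TestHaltonDraws:
    def test_shape_and_reproducibility(self):
        z1 = make_halton_draws(5, 10, 8, seed=4)
        z2 = make_halton_draws(5, 10, 8, seed=4)
        assert z1.shape == (5, 10, 8)
        assert np.array_equal(z1, z2)
        z3 = make_halton_draws(5, 10, 8, seed=5)
        assert not np.array_equal(z1, z3)

    def test_draws_are_roughly_standard_normal(self):
        z = make_halton_draws(20, 500, 3, seed=0).reshape(-1, 3)
        assert np.abs(z.mean(axis=0)).max() < 0.05
        assert np.abs(z.std(axis=0) - 1).max() < 0.05


class TestMixedFit:
    def test_gradient_matches_finite_differences(self, small_panel):
        panel, _ = small_panel
        m = MixedMaxDiffModel(panel, reference="O9", n_draws=8, seed=2)
        rng = np.random.default_rng(5)
        theta = np.concatenate([rng.normal(size=8), rng.uniform(0.2, 1.0, 8)])
        ll, g = m.loglike_score(theta)
        assert ll == pytest.approx(m.loglike(theta), rel=1e-12)
        eps = 1e-6
        for i in range(16):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (m.loglike(tp) - m.loglike(tm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_null_heterogeneity_not_detected_as_significant(self, design99):
        spec = bk.DGPSpec(kind="pooled", design=design99, n_respondents=200,
                          params={"beta": np.linspace(1.5, -1.5, 9) - (-1.5)},
                          seed=21)
        panel, _ = bk.simulate_panel(spec)
        res = bk.fit_mixed(panel, reference="O9", n_draws=100, seed=3)
        z = (res.sigma_abs / res.bse_sigma.replace(0, np.nan)).dropna()
        assert (z < 3).all()

    def test_recovery_within_tolerance(self, mixed_recovery):
        est, _, res = mixed_recovery
        assert (res.mu - est["mu"]).abs().max() < 0.3
        assert (res.sigma_abs - est["sigma"].abs()).abs().max() < 0.4

    def test_draw_count_stability(self, mixed_recovery):
        """Doubling R moves the simulated LL at the estimates only slightly."""
        _, _, res = mixed_recovery
        ll2 = res.loglike_at(2 * res.model.n_draws)
        per_respondent = abs(ll2 - res.llf) / res.model.arrays["n_respondents"]
        assert per_respondent < 0.05


class TestPopulationShares:
    def test_degenerate_mixing_equals_plug_in(self, design99):
        est = datasets.milk_study_mixed_estimates()
        # fabricate a results object via a 1-draw model on a small panel
        spec = bk.DGPSpec(kind="pooled", design=design99, n_respondents=5,
                          params={"beta": np.zeros(9)}, seed=1)
        panel, _ = bk.simulate_panel(spec)
        m = MixedMaxDiffModel(panel, reference="O9", n_draws=1, seed=0)
        from bwskit.mixed import MixedMaxDiffResults
        res = MixedMaxDiffResults(
            model=m, mu=est["mu"], sigma=est["sigma"] * 0.0,
            bse_mu=est["mu"] * 0, bse_sigma=est["mu"] * 0, theta=None,
            cov_params_free=None, llf=0.0, nobs=45)
        shares = res.population_shares(n_draws=200, seed=0)
        plug_in = bk.shares_of_preference(est["mu"].to_numpy(), index=est.index)
        assert np.allclose(shares["mean"], plug_in, atol=1e-12)
        assert np.allclose(shares["sd"], 0.0)

    def test_mean_shares_sum_to_one_and_match_published_ordering(self, design99):
        est = datasets.milk_study_mixed_estimates()
        spec = bk.DGPSpec(kind="pooled", design=design99, n_respondents=5,
                          params={"beta": np.zeros(9)}, seed=1)
        panel, _ = bk.simulate_panel(spec)
        m = MixedMaxDiffModel(panel, reference="O9", n_draws=1, seed=0)
        from bwskit.mixed import MixedMaxDiffResults
        res = MixedMaxDiffResults(
            model=m, mu=est["mu"], sigma=est["sigma"],
            bse_mu=est["mu"] * 0, bse_sigma=est["mu"] * 0, theta=None,
            cov_params_free=None, llf=0.0, nobs=45)
        shares = res.population_shares(n_draws=100000, seed=42)
        assert shares["mean"].sum() == pytest.approx(1.0, abs=1e-12)
        ordering = list(shares["mean"].sort_values(ascending=False).index)
        assert ordering == ["O4", "O2", "O5", "O7", "O8", "O1", "O3", "O6", "O9"]
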
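"""Latent-class EM, information criteria, sweep table, profiling."""

import numpy as np
import pandas as pd
import pytest

import bwskit as bk
from bwskit import datasets
from bwskit.latent import (InformationCriteria, LatentClassMaxDiffModel,
                           delta_percent, information_criteria, profile_classes)

# published class-selection table (classes, LL, AIC, CAIC, BIC and Delta %)
PUBLISHED_SWEEP = pd.DataFrame(
    {
        "classes": [2, 3, 4, 5, 6, 7, 8, 9],
        "loglik": [-2801.49, -2664.97, -2586.98, -2562.83,
                   -2529.5, -2506.58, -2486.44, -2474.2],
        "aic": [5636.98, 5381.94, 5243.95, 5213.66, 5164.99, 5137.15,
                5114.88, 5108.40],
        "caic": [5710.05, 5493.70, 5394.39, 5402.79, 5392.80, 5403.65,
                 5420.06, 5452.26],
        "bic": [5693.05, 5467.7, 5359.39, 5358.79, 5339.8, 5341.65,
                5349.06, 5372.26],
        "d_aic": [np.nan, 4.52, 2.56, 0.58, 0.93, 0.54, 0.43, 0.13],
        "d_caic": [np.nan, 3.79, 1.81, -0.16, 0.18, -0.20, -0.30, -0.59],
        "d_bic": [np.nan, 3.96, 1.98, 0.01, 0.35, -0.03, -0.14, -0.43],
    })


class TestInformationCriteria:
    def test_published_three_class_row(self):
        ic = information_criteria(-2664.97, 26, 200)
        assert ic.aic == pytest.approx(5381.94, abs=0.005)
        assert ic.bic == pytest.approx(5467.70, abs=0.005)
        assert ic.caic == pytest.approx(5493.70, abs=0.005)

    def test_published_two_class_row(self):
        ic = information_criteria(-2801.49, 17, 200)
        assert ic.bic == pytest.approx(5693.05, abs=0.005)
        assert ic.caic == pytest.approx(5710.05, abs=0.005)

    def test_degenerate_zero(self):
        assert information_criteria(0.0, 0, 1) == InformationCriteria(0.0, 0.0, 0.0)

    def test_parameter_count_identity(self, design99):
        # k = C(v-1) + (C-1): 26 free parameters at C=3, 17 at C=2 for v=9
        panel_model = lambda c: LatentClassMaxDiffModel.__new__(LatentClassMaxDiffModel)
        for c, k in [(2, 17), (3, 26), (5, 44)]:
            m = panel_model(c)
            m.n_classes = c
            m.design = design99
            assert m.k_params == k

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, 5, 0)


class TestDeltaColumns:
    def test_deltas_recompute_published_columns(self):
        for col, dcol in [("aic", "d_aic"), ("caic", "d_caic"), ("bic", "d_bic")]:
            d = delta_percent(PUBLISHED_SWEEP[col].to_numpy())
            expected = PUBLISHED_SWEEP[dcol].to_numpy()
            assert np.allclose(d[1:], expected[1:], atol=0.005)

    def test_identical_values_give_zero_delta(self):
        assert delta_percent([100.0, 100.0])[1] == 0.0


@pytest.fixture(scope="module")
def two_class_panel(design99):
    beta = np.array([[2.0, 4.0, 1.0, 3.5, 2.5, 0.5, 2.8, 1.5, 0.0],
                     [0.5, 1.0, 0.2, 0.8, 0.6, -2.0, 0.4, 3.0, 0.0]])
    spec = bk.DGPSpec(kind="latent_class", design=design99, n_respondents=250,
                      params={"class_beta": beta, "class_shares": [0.6, 0.4]},
                      seed=77)
    panel, truth = bk.simulate_panel(spec)
    return panel, truth, beta


class TestEMFit:
    def test_single_class_reduces_to_pooled(self, small_panel):
        panel, _ = small_panel
        lc = LatentClassMaxDiffModel(panel, 1, reference="O9").fit(compute_se=False)
        pooled = bk.fit_pooled(panel, reference="O9", compute_se=False)
        assert lc.llf == pytest.approx(pooled.llf, abs=1e-6)
        assert np.allclose(lc.class_beta.iloc[0], pooled.params, atol=1e-5)
        assert lc.class_shares.iloc[0] == 1.0
        assert (lc.assign() == "class_1").all()

    def test_em_loglik_monotone_and_classes_ordered(self, two_class_panel):
        panel, _, _ = two_class_panel
        res = LatentClassMaxDiffModel(panel, 2, reference="O9").fit(
            n_starts=2, seed=3, compute_se=False)
        trace = np.array(res.em_trace)
        assert (np.diff(trace) >= -1e-8).all()
        assert res.class_shares.is_monotonic_decreasing
        # posteriors and shares live on the simplex
        assert np.allclose(res.posteriors.sum(axis=1), 1.0)
        assert res.class_shares.sum() == pytest.approx(1.0)
        assert (res.class_shares > 0).all()

    def test_two_class_structure_recovered(self, two_class_panel):
        panel, truth, beta = two_class_panel
        res = LatentClassMaxDiffModel(panel, 2, reference="O9").fit(
            n_starts=4, seed=5, compute_se=False)
        assert abs(res.class_shares.iloc[0] - 0.6) < 0.1
        assert np.abs(res.class_beta.to_numpy() - beta).max() < 0.6
        # modal assignment matches the simulated class for most respondents
        hard = res.posteriors.to_numpy().argmax(axis=1)
        acc = (hard == truth["classes"]).mean()
        assert max(acc, 1 - acc) > 0.85

    def test_seeded_fit_is_reproducible(self, two_class_panel):
        panel, _, _ = two_class_panel
        m = LatentClassMaxDiffModel(panel, 2, reference="O9")
        r1 = m.fit(n_starts=2, seed=42, compute_se=False)
        r2 = m.fit(n_starts=2, seed=42, compute_se=False)
        assert r1.llf == r2.llf
        assert r1.class_beta.equals(r2.class_beta)
        assert r1.class_shares.equals(r2.class_shares)

    def test_recovery_of_published_three_class_dgp(self, lc_recovery):
        (class_beta, class_shares), _, truth, res = lc_recovery
        assert np.abs(res.class_shares.to_numpy() - class_shares).max() < 0.05
        err = np.abs(res.class_beta.to_numpy() - class_beta.to_numpy())
        assert err[1].max() < 0.4 and err[2].max() < 0.4

    def test_criteria_attached(self, lc_recovery):
        *_, res = lc_recovery
        expected = information_criteria(res.llf, 26, 2000)
        assert res.criteria == expected


class TestAssignAndShares:
    def test_class_share_of_preference_rows_sum_to_one(self, lc_recovery):
        *_, res = lc_recovery
        sp = res.class_shares_of_preference()
        assert np.allclose(sp.sum(axis=1), 1.0)

    def test_published_class2_share_value(self):
        class_beta, _ = datasets.milk_study_class_solution()
        sp = bk.shares_of_preference(class_beta.loc["class_2"].to_numpy(),
                                     index=class_beta.columns)
        assert sp["O8"] == pytest.approx(0.376, abs=5.1e-4)


class TestProfiling:
    def test_single_class_reproduces_marginals(self):
        assignments = pd.Series(["class_1"] * 50, index=[f"R{i}" for i in range(50)])
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"income": rng.choice(["low", "mid", "high"], 50)},
                           index=assignments.index)
        out = profile_classes(assignments, cov)
        marg = cov["income"].value_counts(normalize=True) * 100
        for level in marg.index:
            assert out.loc[("income", level), "class_1"] == pytest.approx(marg[level])

    def test_blocks_sum_to_100(self, lc_recovery):
        _, panel, _, res = lc_recovery
        out = profile_classes(res.assign(), panel.covariates)
        for cov_name in panel.covariates.columns:
            block = out.loc[cov_name]
            assert np.allclose(block.sum(axis=0), 100.0)

    def test_recovers_simulated_composition(self, lc_recovery):
        (_, class_shares), panel, truth, res = lc_recovery
        out = profile_classes(res.assign(), panel.covariates)
        profiles = datasets.milk_study_covariate_profiles()
        # largest class is well identified: its income composition should be
        # within binomial sampling error of the simulated rates
        n1 = (truth["classes"] == 0).sum()
        for level, p in zip(profiles["income"]["levels"],
                            profiles["income"]["probs"]["class_1"]):
            est = out.loc[("income", level), "class_1"] / 100
            se = np.sqrt(p * (1 - p) / n1)
            assert abs(est - p) < 5 * se + 0.02

    def test_missing_covariates_excluded_pairwise(self):
        assignments = pd.Series(["class_1", "class_1", "class_2"],
                                index=["R1", "R2", "R3"])
        cov = pd.DataFrame({"inc": ["low", None, "high"]},
                           index=["R1", "R2", "R3"])
        out = profile_classes(assignments, cov)
        assert out.attrs["n_included"]["inc"] == 2
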
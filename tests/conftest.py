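"""Shared fixtures: designs, synthetic panels, and session-scoped recovery fits.

The parameter-recovery fits (pooled N=2000, mixed N=1000, latent-class
N=2000) are the expensive parts of the suite; they are computed once per
session and shared by the unit and acceptance tests that assert on them.
"""

import numpy as np
import pytest

import bwskit as bk
from bwskit import datasets
from bwskit.latent import LatentClassMaxDiffModel
from bwskit.mixed import MixedMaxDiffModel


@pytest.fixture(scope="session")
def design99():
    """The study-scale (9, 9, 4) near-BIBD."""
    return bk.generate_design(9, 9, 4, seed=7)


@pytest.fixture(scope="session")
def design332():
    return bk.generate_design(3, 3, 2, seed=0)


@pytest.fixture(scope="session")
def small_panel(design99):
    """A small pooled-DGP panel for quick estimator checks (N=150)."""
    beta = np.array([0.5, 2.0, -0.5, 1.5, 1.0, -1.0, 0.8, 0.2, 0.0])
    spec = bk.DGPSpec(kind="pooled", design=design99, n_respondents=150,
                      params={"beta": beta}, seed=314)
    panel, truth = bk.simulate_panel(spec)
    return panel, truth


@pytest.fixture(scope="session")
def pooled_recovery(design99):
    """Pooled fit on N=2000 simulated from the published mixed-logit means."""
    beta = datasets.milk_study_mixed_estimates()["mu"].to_numpy()
    spec = bk.DGPSpec(kind="pooled", design=design99, n_respondents=2000,
                      params={"beta": beta}, seed=1001)
    panel, truth = bk.simulate_panel(spec)
    res = bk.fit_pooled(panel, reference="O9", compute_se=False)
    return beta, panel, res


@pytest.fixture(scope="session")
def mixed_recovery(design99):
    """Two-stage mixed-logit fit on N=1000 from the published (mu, sigma)."""
    est = datasets.milk_study_mixed_estimates()
    spec = bk.DGPSpec(
        kind="mixed", design=design99, n_respondents=1000,
        params={"mu": est["mu"].to_numpy(), "sigma": est["sigma"].to_numpy()},
        seed=2024)
    panel, truth = bk.simulate_panel(spec)
    stage1 = MixedMaxDiffModel(panel, reference="O9", n_draws=64, seed=5).fit(
        compute_se=False)
    res = MixedMaxDiffModel(panel, reference="O9", n_draws=1000, seed=5).fit(
        start=stage1.theta, compute_se=False)
    return est, panel, res


@pytest.fixture(scope="session")
def lc_recovery(design99):
    """3-class EM fit on N=2000 from the published latent-class solution."""
    class_beta, class_shares = datasets.milk_study_class_solution()
    spec = bk.DGPSpec(
        kind="latent_class", design=design99, n_respondents=2000,
        params={"class_beta": class_beta.to_numpy(), "class_shares": class_shares},
        covariates=datasets.milk_study_covariate_profiles(), seed=99)
    panel, truth = bk.simulate_panel(spec)
    res = LatentClassMaxDiffModel(panel, 3, reference="O9").fit(
        n_starts=3, seed=11, compute_se=False)
    return (class_beta, class_shares), panel, truth, res
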
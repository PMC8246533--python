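"""Mixed-logit maxdiff estimation by maximum simulated likelihood.

Preference heterogeneity is modelled with respondent-specific utilities

    beta_n = mu + sigma * z_n,        z_n ~ N(0, I)  (independent per option),

with the reference option pinned at mu = sigma = 0.  The panel structure is
respected: a respondent's likelihood is the product of their card
probabilities at a common coefficient draw, averaged over R draws,

    L_n = (1/R) sum_r prod_c P(best_c, worst_c | mu + sigma * z_nr).

Draws are scrambled Halton sequences (one dimension per random coefficient,
a contiguous block of R points per respondent), transformed to normals —
the standard low-discrepancy scheme for simulated likelihood.  The
likelihood depends on sigma only through |sigma|; raw (possibly negative)
estimates are reported alongside their magnitudes since the sign is not
identified.

Analytic gradients propagate through the draw average; standard errors come
from the inverse observed information of the simulated log-likelihood
(central-difference Hessian of the analytic score).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, softmax
from scipy.stats import norm, qmc

from .maxdiff import MaxDiffModel, card_logprob_grad, card_logprobs

__all__ = [
    "make_halton_draws",
    "simulated_loglik",
    "MixedMaxDiffModel",
    "MixedMaxDiffResults",
    "fit_mixed",
]


def make_halton_draws(n_respondents: int, n_draws: int, n_dims: int,
                      seed: int | None = None) -> np.ndarray:
    """Standard-normal scrambled Halton draws, shape (N, R, n_dims).

    Respondent ``n`` owns the contiguous block of rows ``[n*R, (n+1)*R)`` of
    one Halton stream, so draws are reproducible and respondent-specific.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    sampler = qmc.Halton(d=n_dims, scramble=True, seed=seed)
    u = sampler.random(n_respondents * n_draws)
    # clip away exact 0/1 before the normal quantile transform
    eps = 1e-12
    z = norm.ppf(np.clip(u, eps, 1 - eps))
    return z.reshape(n_respondents, n_draws, n_dims)


def _respondent_loglik(beta_draws, arrays):
    """Per-respondent, per-draw panel log-likelihood, shape (N, R).

    ``beta_draws``: (N, R, v) utilities per respondent and draw.
    """
    resp = arrays["resp_idx"]
    shown = arrays["shown"]
    n, r, _ = beta_draws.shape
    ridx = np.arange(r)[None, :, None]
    util = beta_draws[resp[:, None, None], ridx, shown[:, None, :]]  # (n_obs, R, J)
    lp = card_logprobs(util, arrays["best_pos"][:, None], arrays["worst_pos"][:, None])
    return _segment_sum_rows(lp, resp, n)


def _segment_sum_rows(values, resp, n):
    """Sum rows of ``values`` (n_obs, R) by respondent code -> (N, R)."""
    n_obs = values.shape[0]
    if n_obs % n == 0:
        b = n_obs // n
        blocks = resp.reshape(n, b)
        if (blocks == blocks[:, :1]).all() and (blocks[:, 0] == np.arange(n)).all():
            return values.reshape(n, b, -1).sum(axis=1)
    out = np.zeros((n, values.shape[1]))
    np.add.at(out, resp, values)
    return out


def simulated_loglik(mu, sigma, panel_or_arrays, draws) -> float:
    """Simulated maxdiff log-likelihood at (mu, sigma) with explicit draws.

    ``draws`` is an (N, R, v) array of standard-normal variates;
    beta_nr = mu + |sigma| * draws[n, r].  With sigma = 0 this equals the
    pooled log-likelihood at beta = mu exactly.
    """
    arrays = panel_or_arrays if isinstance(panel_or_arrays, dict) else panel_or_arrays.to_arrays()
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if draws.ndim != 3:
        raise ValueError("draws must have shape (N, R, v)")
    n, r, v = draws.shape
    if r < 1:
        raise ValueError("need at least one draw")
    beta_draws = mu[None, None, :] + np.abs(sigma)[None, None, :] * draws
    ll_nr = _respondent_loglik(beta_draws, arrays)
    return float(np.sum(logsumexp(ll_nr, axis=1) - np.log(r)))


class MixedMaxDiffModel:
    """Mixed-logit maxdiff model with independent normal coefficients.

    Parameters
    ----------
    panel : ResponsePanel
    reference : str, optional
        Item with mu = sigma = 0 (default: last design item).
    n_draws : int
        Halton draws per respondent (R).  500 by default.
    seed : int, optional
        Seed for the scrambled Halton stream; fixing it makes the simulated
        likelihood (and hence the fit) exactly reproducible.
    """

    def __init__(self, panel, reference: str | None = None, n_draws: int = 500,
                 seed: int | None = None):
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        self.panel = panel
        self.design = panel.design
        self.arrays = panel.to_arrays()
        self.reference = reference if reference is not None else self.design.items[-1]
        self.ref_idx = self.design.index_of(self.reference)
        self.n_draws = int(n_draws)
        self.seed = seed
        v = self.design.v
        self.free = np.array([i for i in range(v) if i != self.ref_idx])
        z = make_halton_draws(self.arrays["n_respondents"], self.n_draws,
                              len(self.free), seed=seed)
        # embed into full item space; the reference draws stay at zero
        self.draws = np.zeros((z.shape[0], z.shape[1], v))
        self.draws[:, :, self.free] = z

    # -- parameter packing: theta = (mu_free, sigma_free) ---------------
    def _unpack(self, theta):
        p = len(self.free)
        mu = np.zeros(self.design.v)
        sigma = np.zeros(self.design.v)
        mu[self.free] = theta[:p]
        sigma[self.free] = theta[p:]
        return mu, sigma

    def loglike(self, theta) -> float:
        mu, sigma = self._unpack(theta)
        return simulated_loglik(mu, sigma, self.arrays, self.draws)

    def loglike_score(self, theta):
        """(simulated LL, analytic gradient in theta)."""
        mu, sigma = self._unpack(theta)
        arrays = self.arrays
        resp = arrays["resp_idx"]
        shown = arrays["shown"]
        beta_draws = mu[None, None, :] + np.abs(sigma)[None, None, :] * self.draws
        n, r, v = beta_draws.shape
        ridx = np.arange(r)[None, :, None]
        util = beta_draws[resp[:, None, None], ridx, shown[:, None, :]]
        lp, g = card_logprob_grad(util, arrays["best_pos"][:, None],
                                  arrays["worst_pos"][:, None])
        ll_nr = _segment_sum_rows(lp, resp, n)
        ll_n = logsumexp(ll_nr, axis=1) - np.log(r)
        w = softmax(ll_nr, axis=1)          # (N, R) posterior draw weights
        gw = g * w[resp][:, :, None]        # (n_obs, R, J)
        # scatter the per-position gradients back onto item indices
        shown_rep = np.broadcast_to(shown[:, None, :], gw.shape)
        g_mu = np.bincount(shown_rep.ravel(), weights=gw.ravel(), minlength=v)
        z_obs = self.draws[resp[:, None, None], ridx, shown[:, None, :]]
        g_sigma = np.bincount(shown_rep.ravel(), weights=(gw * z_obs).ravel(),
                              minlength=v)
        sgn = np.sign(sigma)
        g_sigma = g_sigma * sgn
        return float(ll_n.sum()), np.concatenate([g_mu[self.free], g_sigma[self.free]])

    def hessian(self, theta, eps: float = 1e-4) -> np.ndarray:
        p = len(theta)
        h = np.zeros((p, p))
        for i in range(p):
            tp = np.array(theta, float)
            tm = tp.copy()
            tp[i] += eps
            tm[i] -= eps
            h[i] = (self.loglike_score(tp)[1] - self.loglike_score(tm)[1]) / (2 * eps)
        return (h + h.T) / 2.0

    def fit(self, start=None, gtol: float = 1e-5, maxiter: int = 400,
            compute_se: bool = True, zero_sd_restart: float = 0.5
            ) -> "MixedMaxDiffResults":
        p = len(self.free)
        if start is None:
            pooled = MaxDiffModel(self.panel, reference=self.reference).fit(compute_se=False)
            theta0 = np.concatenate([pooled.theta, np.full(p, 0.1)])
        else:
            theta0 = np.asarray(start, dtype=float)

        def neg(t):
            ll, g = self.loglike_score(t)
            return -ll, -g

        def solve(t0):
            res = optimize.minimize(neg, t0, jac=True, method="L-BFGS-B",
                                    options={"gtol": gtol, "ftol": 1e-11,
                                             "maxiter": maxiter})
            if not (res.success or np.max(np.abs(res.jac)) < 1e-2):
                raise RuntimeError(
                    f"mixed-logit estimation did not converge: {res.message} "
                    f"(|grad|max = {np.max(np.abs(res.jac)):.2e})")
            return res

        res = solve(theta0)
        # |sigma| has a non-differentiable point at zero that can trap the
        # search in a spurious local mode; restart collapsed components at a
        # moderate scale and keep the refit only if it improves the LL
        if zero_sd_restart:
            collapsed = np.abs(res.x[p:]) < 0.05
            if collapsed.any():
                t0 = res.x.copy()
                t0[p:][collapsed] = zero_sd_restart
                try:
                    res2 = solve(t0)
                    if res2.fun < res.fun:
                        res = res2
                except RuntimeError:
                    pass
        theta = res.x
        bse = np.full(2 * p, np.nan)
        cov = None
        if compute_se:
            hess = self.hessian(theta)
            try:
                cov = np.linalg.inv(-hess)
                with np.errstate(invalid="ignore"):
                    bse = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                pass
        mu, sigma = self._unpack(theta)
        items = list(self.design.items)
        bse_mu = np.zeros(self.design.v)
        bse_sigma = np.zeros(self.design.v)
        bse_mu[self.free] = bse[:p]
        bse_sigma[self.free] = bse[p:]
        return MixedMaxDiffResults(
            model=self,
            mu=pd.Series(mu, index=items),
            sigma=pd.Series(sigma, index=items),
            bse_mu=pd.Series(bse_mu, index=items),
            bse_sigma=pd.Series(bse_sigma, index=items),
            theta=theta,
            cov_params_free=cov,
            llf=-res.fun,
            nobs=len(self.arrays["best_pos"]),
        )


class MixedMaxDiffResults:
    """Fitted mixed-logit maxdiff model."""

    def __init__(self, model, mu, sigma, bse_mu, bse_sigma, theta,
                 cov_params_free, llf, nobs):
        self.model = model
        self.mu = mu
        self.sigma = sigma              # raw estimates (sign unidentified)
        self.sigma_abs = sigma.abs()
        self.bse_mu = bse_mu
        self.bse_sigma = bse_sigma
        self.theta = theta
        self.cov_params_free = cov_params_free
        self.llf = llf
        self.nobs = nobs

    @property
    def reference(self) -> str:
        return self.model.reference

    def loglike_at(self, n_draws: int, seed: int | None = None) -> float:
        """Re-evaluate the simulated LL at the estimates with other draws."""
        z = make_halton_draws(self.model.arrays["n_respondents"], n_draws,
                              len(self.model.free),
                              seed=self.model.seed if seed is None else seed)
        draws = np.zeros((z.shape[0], z.shape[1], self.model.design.v))
        draws[:, :, self.model.free] = z
        return simulated_loglik(self.mu.to_numpy(), self.sigma.to_numpy(),
                                self.model.arrays, draws)

    def population_shares(self, n_draws: int = 10000, seed: int | None = None):
        """Mean and SD of the shares of preference over the mixing distribution.

        Draws beta ~ N(mu, diag(sigma^2)) (reference fixed at zero), applies
        the share-of-preference softmax per draw, and averages.  Returns a
        DataFrame with ``mean`` (sums to one) and ``sd`` columns.
        """
        rng = np.random.default_rng(seed)
        v = self.model.design.v
        z = rng.standard_normal((n_draws, v))
        z[:, self.model.ref_idx] = 0.0
        beta = self.mu.to_numpy()[None, :] + self.sigma_abs.to_numpy()[None, :] * z
        s = softmax(beta, axis=1)
        return pd.DataFrame({"mean": s.mean(axis=0), "sd": s.std(axis=0)},
                            index=self.mu.index)

    def summary(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            z_mu = self.mu / self.bse_mu.replace(0.0, np.nan)
            z_sigma = self.sigma / self.bse_sigma.replace(0.0, np.nan)
        tab = pd.DataFrame({
            "mean": self.mu, "mean_se": self.bse_mu, "mean_z": z_mu,
            "sd": self.sigma, "sd_se": self.bse_sigma, "sd_z": z_sigma,
        })
        tab.attrs["loglik"] = self.llf
        tab.attrs["nobs"] = self.nobs
        tab.attrs["reference"] = self.reference
        tab.attrs["n_draws"] = self.model.n_draws
        tab.attrs["seed"] = self.model.seed
        return tab

    def to_dict(self) -> dict:
        return {
            "kind": "mixed_maxdiff",
            "items": list(self.mu.index),
            "reference": self.reference,
            "mu": [float(x) for x in self.mu],
            "sigma": [float(x) for x in self.sigma],
            "se_mu": [float(x) for x in self.bse_mu],
            "se_sigma": [float(x) for x in self.bse_sigma],
            "loglik": float(self.llf),
            "n_obs": int(self.nobs),
            "draws": {"count": self.model.n_draws, "scheme": "scrambled_halton",
                      "seed": self.model.seed},
        }


def fit_mixed(panel, reference=None, n_draws: int = 500, seed: int | None = None,
              **kwargs) -> MixedMaxDiffResults:
    """Convenience wrapper for ``MixedMaxDiffModel(...).fit(...)``."""
    return MixedMaxDiffModel(panel, reference=reference, n_draws=n_draws,
                             seed=seed).fit(**kwargs)
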
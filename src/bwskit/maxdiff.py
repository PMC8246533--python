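"""Maxdiff (best-worst) choice model: probabilities and pooled estimation.

Under the maxdiff model a respondent facing a card with shown options
``S`` (|S| = J) evaluates every ordered pair (i, j), i != j, and picks the
pair maximizing the utility difference.  With option utilities ``beta`` the
choice probability is

    P(i, j) = exp(beta_i - beta_j) / sum_{(k,l), k != l} exp(beta_k - beta_l).

One option's utility is pinned to zero (the reference) for identification;
probabilities are invariant to adding a constant to all utilities.

The normalizing constant factorizes,

    sum_{k != l} exp(u_k - u_l) = (sum_k exp(u_k)) (sum_l exp(-u_l)) - J,

which this module exploits (after centering the utilities for overflow
safety) so no J x J pair array is ever materialized in the likelihood.

``MaxDiffModel`` is the pooled (conditional logit) estimator: one utility
vector shared by all respondents, maximum likelihood by quasi-Newton with
analytic gradients, standard errors from the inverse observed information.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import softmax

__all__ = [
    "pair_probabilities",
    "card_logprobs",
    "loglik_pooled",
    "shares_of_preference",
    "MaxDiffModel",
    "MaxDiffResults",
    "fit_pooled",
]


# ---------------------------------------------------------------------------
# probability kernels
# ---------------------------------------------------------------------------

def _pair_parts(util: np.ndarray):
    """Stable pieces of the maxdiff normalizer for utilities ``util`` (..., J).

    Returns (x, logsplus, logsminus, logdenom) with x the centered utilities
    and logdenom = log sum_{k != l} exp(u_k - u_l), computed in log space
    from the factorization sum = (sum e^u)(sum e^-u) - J (shift-free).
    """
    center = (util.max(axis=-1, keepdims=True) + util.min(axis=-1, keepdims=True)) / 2.0
    x = util - center
    ls = np.log(np.exp(x).sum(axis=-1))
    lm = np.log(np.exp(-x).sum(axis=-1))
    logdenom = ls + lm + np.log1p(-util.shape[-1] * np.exp(-(ls + lm)))
    return x, ls, lm, logdenom


def card_logprobs(util: np.ndarray, best_pos, worst_pos) -> np.ndarray:
    """log P(best, worst) for utility arrays of shape (..., J).

    ``best_pos``/``worst_pos`` index positions within the trailing axis and
    broadcast against the leading axes.
    """
    x, _, _, logdenom = _pair_parts(util)
    ub = np.take_along_axis(x, np.asarray(best_pos)[..., None], axis=-1)[..., 0]
    uw = np.take_along_axis(x, np.asarray(worst_pos)[..., None], axis=-1)[..., 0]
    return ub - uw - logdenom


def card_logprob_grad(util: np.ndarray, best_pos, worst_pos):
    """(logp, d logp / d util) for utilities of shape (..., J)."""
    x, ls, lm, logdenom = _pair_parts(util)
    bp = np.asarray(best_pos)[..., None]
    wp = np.asarray(worst_pos)[..., None]
    ub = np.take_along_axis(x, bp, axis=-1)[..., 0]
    uw = np.take_along_axis(x, wp, axis=-1)[..., 0]
    logp = ub - uw - logdenom
    # d log denom / d u_j = (row margin - column margin) of the pair matrix:
    # row_j = (e^{x_j} S- - 1)/D, col_j = (e^{-x_j} S+ - 1)/D, all in log space
    ld = logdenom[..., None]
    row = np.exp(x + (lm - logdenom)[..., None]) - np.exp(-ld)
    col = np.exp(-x + (ls - logdenom)[..., None]) - np.exp(-ld)
    grad = col - row
    np.put_along_axis(grad, bp, np.take_along_axis(grad, bp, axis=-1) + 1.0, axis=-1)
    np.put_along_axis(grad, wp, np.take_along_axis(grad, wp, axis=-1) - 1.0, axis=-1)
    return logp, grad


def pair_probabilities(beta, shown) -> pd.Series:
    """Probability of every ordered (best, worst) pair on one card.

    ``beta`` holds utilities for all items (indexable by the entries of
    ``shown``); pairs are enumerated lexicographically over the sorted shown
    set, matching :func:`bwskit.panel.expand_pairs`.
    """
    beta = np.asarray(beta, dtype=float)
    shown = sorted(int(i) for i in shown)
    u = beta[shown]
    diffs = u[:, None] - u[None, :]
    mask = ~np.eye(len(shown), dtype=bool)
    w = np.exp(diffs - diffs[mask].max())
    w[~mask] = 0.0
    w /= w.sum()
    idx = [(i, j) for i in shown for j in shown if i != j]
    vals = [w[a, b] for a in range(len(shown)) for b in range(len(shown)) if a != b]
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["best", "worst"]))


def shares_of_preference(beta, index=None) -> pd.Series:
    """Share of preference: softmax of the option utilities.

    S_i = exp(beta_i) / sum_m exp(beta_m).  Shares sum to one and are
    interpretable on a ratio scale (S_i / S_j = exp(beta_i - beta_j)).
    """
    s = softmax(np.asarray(beta, dtype=float))
    return pd.Series(s, index=index)


# ---------------------------------------------------------------------------
# pooled likelihood and estimator
# ---------------------------------------------------------------------------

def _free_to_full(theta, v, ref):
    beta = np.zeros(v)
    beta[np.arange(v) != ref] = theta
    return beta


def loglik_pooled(beta, panel_or_arrays, weights=None, grad: bool = False):
    """Pooled maxdiff log-likelihood (and gradient in the full beta space).

    Accepts a ``ResponsePanel`` or the dict from
    :meth:`ResponsePanel.to_arrays`; ``weights`` are optional per-card
    weights (used by the latent-class M-step).
    """
    arrays = (panel_or_arrays if isinstance(panel_or_arrays, dict)
              else panel_or_arrays.to_arrays())
    beta = np.asarray(beta, dtype=float)
    shown = arrays["shown"]
    util = beta[shown]
    if not grad:
        lp = card_logprobs(util, arrays["best_pos"], arrays["worst_pos"])
        return float(lp @ weights) if weights is not None else float(lp.sum())
    lp, g = card_logprob_grad(util, arrays["best_pos"], arrays["worst_pos"])
    if weights is not None:
        ll = float(lp @ weights)
        g = g * weights[:, None]
    else:
        ll = float(lp.sum())
    full = np.zeros_like(beta)
    np.add.at(full, shown.ravel(), g.ravel())
    return ll, full


class MaxDiffModel:
    """Pooled (conditional logit) maxdiff model.

    Parameters
    ----------
    panel : ResponsePanel
        Validated best-worst responses.
    reference : str, optional
        Item label whose utility is pinned to zero; defaults to the last
        item of the design.
    """

    def __init__(self, panel, reference: str | None = None):
        self.panel = panel
        self.design = panel.design
        self.arrays = panel.to_arrays()
        v = self.design.v
        self.reference = reference if reference is not None else self.design.items[-1]
        self.ref_idx = self.design.index_of(self.reference)
        self.n_params = v - 1
        self.exog_names = [lab for i, lab in enumerate(self.design.items) if i != self.ref_idx]

    # -- likelihood in the free parameterization -----------------------
    def loglike(self, theta, weights=None) -> float:
        beta = _free_to_full(theta, self.design.v, self.ref_idx)
        return loglik_pooled(beta, self.arrays, weights=weights)

    def score(self, theta, weights=None) -> np.ndarray:
        beta = _free_to_full(theta, self.design.v, self.ref_idx)
        _, g = loglik_pooled(beta, self.arrays, weights=weights, grad=True)
        return np.delete(g, self.ref_idx)

    def hessian(self, theta, weights=None, eps: float = 1e-5) -> np.ndarray:
        """Observed-information Hessian by central differences of the score."""
        p = len(theta)
        h = np.zeros((p, p))
        for i in range(p):
            tp = np.array(theta, dtype=float)
            tm = tp.copy()
            tp[i] += eps
            tm[i] -= eps
            h[i] = (self.score(tp, weights) - self.score(tm, weights)) / (2 * eps)
        return (h + h.T) / 2.0

    def _check_separation(self) -> list[str]:
        arr = self.arrays
        flagged = []
        for i in range(self.design.v):
            appears = (arr["shown"] == i).sum()
            if appears == 0:
                continue
            best = (arr["shown"][np.arange(len(arr["best_pos"])), arr["best_pos"]] == i).sum()
            worst = (arr["shown"][np.arange(len(arr["worst_pos"])), arr["worst_pos"]] == i).sum()
            if best == appears or worst == appears:
                flagged.append(self.design.items[i])
        return flagged

    def fit(self, start=None, weights=None, gtol: float = 1e-6,
            maxiter: int = 500, compute_se: bool = True) -> "MaxDiffResults":
        sep = self._check_separation() if weights is None else []
        if sep:
            warnings.warn(
                f"options {sep} are always best or always worst wherever shown; "
                "their utilities are not finitely identified and standard errors "
                "will not be finite", RuntimeWarning)
        theta0 = np.zeros(self.n_params) if start is None else np.asarray(start, float)
        res = optimize.minimize(
            lambda t: -self.loglike(t, weights),
            theta0,
            jac=lambda t: -self.score(t, weights),
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        theta = res.x
        cov = None
        bse = np.full(self.n_params, np.nan)
        if compute_se:
            hess = self.hessian(theta, weights)
            try:
                cov = np.linalg.inv(-hess)
                with np.errstate(invalid="ignore"):
                    bse = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                cov = np.full((self.n_params, self.n_params), np.nan)
        beta = _free_to_full(theta, self.design.v, self.ref_idx)
        return MaxDiffResults(
            model=self,
            params=pd.Series(beta, index=list(self.design.items)),
            theta=theta,
            bse=pd.Series(np.insert(bse, self.ref_idx, 0.0), index=list(self.design.items)),
            cov_params_free=cov,
            llf=-res.fun,
            nobs=len(self.arrays["best_pos"]),
            converged=bool(res.success or np.max(np.abs(res.jac)) < 1e-4),
            separated=sep,
        )


class MaxDiffResults:
    """Fitted pooled maxdiff model: utilities, SEs, likelihood, shares."""

    def __init__(self, model, params, theta, bse, cov_params_free, llf, nobs,
                 converged, separated=()):
        self.model = model
        self.params = params          # full beta with reference at 0
        self.theta = theta            # free parameters (reference dropped)
        self.bse = bse
        self.cov_params_free = cov_params_free
        self.llf = llf
        self.nobs = nobs
        self.converged = converged
        self.separated = list(separated)

    @property
    def reference(self) -> str:
        return self.model.reference

    def shares(self) -> pd.Series:
        """Shares of preference (softmax of the fitted utilities)."""
        return shares_of_preference(self.params.to_numpy(), index=self.params.index)

    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse.replace(0.0, np.nan)

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "coef": self.params,
            "std_err": self.bse,
            "z": self.zvalues(),
            "share_of_preference": self.shares(),
        })
        tab.loc[self.reference, ["std_err", "z"]] = np.nan
        tab.attrs["loglik"] = self.llf
        tab.attrs["nobs"] = self.nobs
        tab.attrs["reference"] = self.reference
        return tab

    def to_dict(self) -> dict:
        return {
            "kind": "pooled_maxdiff",
            "items": list(self.params.index),
            "reference": self.reference,
            "beta": [float(x) for x in self.params],
            "se": [float(x) for x in self.bse],
            "covariance_free": None if self.cov_params_free is None
            else np.asarray(self.cov_params_free).tolist(),
            "loglik": float(self.llf),
            "n_obs": int(self.nobs),
            "converged": bool(self.converged),
        }


def fit_pooled(panel, reference: str | None = None, **kwargs) -> MaxDiffResults:
    """Convenience wrapper: ``MaxDiffModel(panel, reference).fit(**kwargs)``."""
    return MaxDiffModel(panel, reference=reference).fit(**kwargs)
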
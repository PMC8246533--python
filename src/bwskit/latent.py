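"""Latent-class maxdiff estimation by EM, model selection, and profiling.

The finite-mixture model assumes C unobserved respondent classes, each with
its own utility vector beta_c (reference pinned to zero per class) and a
mixture share pi_c.  A respondent's likelihood is

    L_n = sum_c pi_c prod_cards P(best, worst | beta_c),

maximized by expectation-maximization: the E-step computes posterior class
memberships, the M-step refits each class's pooled maxdiff model with the
posteriors as card weights and sets pi_c to the mean posterior.  The
log-likelihood is non-decreasing across iterations (asserted), classes are
canonically ordered by descending share, and the best of several random
starts is returned.

Class-count selection uses AIC / BIC / CAIC with k = C(v-1) + (C-1) free
parameters and n = number of respondents, plus the percent-improvement
columns Delta_IC(C) = 100 (IC(C-1) - IC(C)) / IC(C-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .maxdiff import MaxDiffModel, card_logprobs, shares_of_preference

__all__ = [
    "information_criteria",
    "delta_percent",
    "LatentClassMaxDiffModel",
    "LatentClassResults",
    "class_sweep",
    "profile_classes",
    "InformationCriteria",
]


@dataclass(frozen=True)
class InformationCriteria:
    aic: float
    bic: float
    caic: float


def information_criteria(loglik: float, k_params: int, n: int) -> InformationCriteria:
    """AIC = -2LL + 2k;  BIC = -2LL + k ln n;  CAIC = -2LL + k (ln n + 1).

    ``n`` is the number of respondents (the independent sampling units of
    the panel likelihood), not the number of cards.
    """
    if n < 1 or k_params < 0:
        raise ValueError("need n >= 1 and k_params >= 0")
    m2ll = -2.0 * loglik
    ln = np.log(n)
    return InformationCriteria(
        aic=m2ll + 2.0 * k_params,
        bic=m2ll + k_params * ln,
        caic=m2ll + k_params * (ln + 1.0),
    )


def delta_percent(values) -> np.ndarray:
    """Percent improvement over the previous row: 100 (x[i-1] - x[i]) / x[i-1]."""
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    out[1:] = 100.0 * (x[:-1] - x[1:]) / x[:-1]
    return out


def _respondent_class_loglik(beta, arrays):
    """Per-respondent panel log-likelihood at one utility vector."""
    util = np.asarray(beta, dtype=float)[arrays["shown"]]
    lp = card_logprobs(util, arrays["best_pos"], arrays["worst_pos"])
    out = np.zeros(arrays["n_respondents"])
    np.add.at(out, arrays["resp_idx"], lp)
    return out


class LatentClassMaxDiffModel:
    """Latent-class maxdiff model fitted by EM.

    Parameters
    ----------
    panel : ResponsePanel
    n_classes : int
        Number of latent classes C >= 1 (C = 1 reduces to the pooled model).
    reference : str, optional
        Utility pinned to zero within every class.
    """

    def __init__(self, panel, n_classes: int, reference: str | None = None):
        if n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        self.panel = panel
        self.design = panel.design
        self.n_classes = int(n_classes)
        self.reference = reference if reference is not None else self.design.items[-1]
        self.ref_idx = self.design.index_of(self.reference)
        self.arrays = panel.to_arrays()
        self._pooled = MaxDiffModel(panel, reference=self.reference)

    @property
    def k_params(self) -> int:
        return self.n_classes * (self.design.v - 1) + (self.n_classes - 1)

    # ------------------------------------------------------------------
    def _em_once(self, theta0, pi0, max_iter, tol):
        arrays = self.arrays
        resp = arrays["resp_idx"]
        c = self.n_classes
        thetas = [np.array(t, dtype=float) for t in theta0]
        pi = np.array(pi0, dtype=float)
        pi = pi / pi.sum()
        ll_old = -np.inf
        trace = []
        for _ in range(max_iter):
            betas = [self._pooled_beta(t) for t in thetas]
            lmat = np.column_stack([_respondent_class_loglik(b, arrays) for b in betas])
            joint = lmat + np.log(pi)[None, :]
            ll = float(logsumexp(joint, axis=1).sum())
            assert ll >= ll_old - 1e-8, "EM log-likelihood decreased"
            trace.append(ll)
            post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
            if ll - ll_old < tol and len(trace) > 1:
                ll_old = ll
                break
            ll_old = ll
            pi = post.mean(axis=0)
            if np.any(pi < 1e-6):
                return None, None, None, trace, True  # empty class: ask for restart
            for j in range(c):
                w = post[resp, j]
                fit = self._pooled.fit(start=thetas[j], weights=w, compute_se=False)
                thetas[j] = fit.theta
        return thetas, pi, post, trace, False

    def _pooled_beta(self, theta):
        beta = np.zeros(self.design.v)
        beta[np.arange(self.design.v) != self.ref_idx] = theta
        return beta

    def fit(self, n_starts: int = 20, seed: int | None = None,
            max_em_iter: int = 500, tol: float = 1e-7,
            compute_se: bool = True) -> "LatentClassResults":
        c = self.n_classes
        pooled = self._pooled.fit(compute_se=False)
        if c == 1:
            pooled_se = self._pooled.fit(compute_se=compute_se)
            return self._wrap_single(pooled_se)
        rng = np.random.default_rng(seed)
        best = None
        restarts = 0
        attempts = 0
        while attempts < n_starts + restarts and restarts < 3 * n_starts:
            attempts += 1
            theta0 = [pooled.theta + rng.normal(scale=1.0, size=len(pooled.theta))
                      for _ in range(c)]
            pi0 = rng.dirichlet(np.full(c, 5.0))
            thetas, pi, post, trace, empty = self._em_once(theta0, pi0, max_em_iter, tol)
            if empty:
                restarts += 1
                warnings.warn("EM start collapsed a class; restarting", RuntimeWarning)
                continue
            if best is None or trace[-1] > best[3][-1]:
                best = (thetas, pi, post, trace)
        if best is None:
            raise RuntimeError("all EM starts collapsed a class; try fewer classes")
        thetas, pi, post, trace = best
        # canonical ordering: descending class share
        order = np.argsort(-pi, kind="stable")
        thetas = [thetas[j] for j in order]
        pi = pi[order]
        post = post[:, order]
        bse = None
        if compute_se:
            bse = []
            for j in range(c):
                w = post[self.arrays["resp_idx"], j]
                fit = self._pooled.fit(start=thetas[j], weights=w, compute_se=True)
                bse.append(fit.bse)
        ll = trace[-1]
        crit = information_criteria(ll, self.k_params, self.arrays["n_respondents"])
        items = list(self.design.items)
        class_beta = pd.DataFrame(
            [self._pooled_beta(t) for t in thetas],
            index=[f"class_{j + 1}" for j in range(c)], columns=items)
        return LatentClassResults(
            model=self,
            class_beta=class_beta,
            class_shares=pd.Series(pi, index=class_beta.index),
            posteriors=pd.DataFrame(post, index=self.arrays["resp_ids"],
                                    columns=class_beta.index),
            class_bse=None if bse is None else pd.DataFrame(
                [b.to_numpy() for b in bse], index=class_beta.index, columns=items),
            llf=ll, criteria=crit, k_params=self.k_params,
            nobs=len(self.arrays["best_pos"]),
            n_respondents=self.arrays["n_respondents"],
            em_trace=trace,
        )

    def _wrap_single(self, pooled_fit) -> "LatentClassResults":
        items = list(self.design.items)
        n = self.arrays["n_respondents"]
        crit = information_criteria(pooled_fit.llf, self.k_params, n)
        return LatentClassResults(
            model=self,
            class_beta=pd.DataFrame([pooled_fit.params.to_numpy()],
                                    index=["class_1"], columns=items),
            class_shares=pd.Series([1.0], index=["class_1"]),
            posteriors=pd.DataFrame(np.ones((n, 1)),
                                    index=self.arrays["resp_ids"], columns=["class_1"]),
            class_bse=pd.DataFrame([pooled_fit.bse.to_numpy()],
                                   index=["class_1"], columns=items),
            llf=pooled_fit.llf, criteria=crit, k_params=self.k_params,
            nobs=pooled_fit.nobs, n_respondents=n, em_trace=[pooled_fit.llf],
        )


class LatentClassResults:
    """Fitted latent-class maxdiff model."""

    def __init__(self, model, class_beta, class_shares, posteriors, class_bse,
                 llf, criteria, k_params, nobs, n_respondents, em_trace):
        self.model = model
        self.class_beta = class_beta        # C x v, reference column at 0
        self.class_shares = class_shares    # pi_c, descending
        self.posteriors = posteriors        # N x C
        self.class_bse = class_bse
        self.llf = llf
        self.criteria = criteria
        self.k_params = k_params
        self.nobs = nobs
        self.n_respondents = n_respondents
        self.em_trace = list(em_trace)

    @property
    def n_classes(self) -> int:
        return len(self.class_shares)

    def assign(self) -> pd.Series:
        """Modal-posterior hard class assignment per respondent."""
        return self.posteriors.idxmax(axis=1)

    def class_shares_of_preference(self) -> pd.DataFrame:
        """Per-class shares of preference (each row sums to one)."""
        rows = {cls: shares_of_preference(self.class_beta.loc[cls].to_numpy(),
                                          index=self.class_beta.columns)
                for cls in self.class_beta.index}
        return pd.DataFrame(rows).T

    def summary(self) -> pd.DataFrame:
        sp = self.class_shares_of_preference()
        blocks = []
        for cls in self.class_beta.index:
            blk = pd.DataFrame({
                ("coef", cls): self.class_beta.loc[cls],
                ("sp", cls): sp.loc[cls],
            })
            if self.class_bse is not None:
                blk[("std_err", cls)] = self.class_bse.loc[cls]
            blocks.append(blk)
        tab = pd.concat(blocks, axis=1)
        tab.attrs["loglik"] = self.llf
        tab.attrs["class_shares"] = self.class_shares.to_dict()
        tab.attrs["criteria"] = self.criteria
        return tab

    def to_dict(self) -> dict:
        return {
            "kind": "latent_class_maxdiff",
            "items": list(self.class_beta.columns),
            "reference": self.model.reference,
            "n_classes": self.n_classes,
            "class_shares": [float(x) for x in self.class_shares],
            "class_beta": self.class_beta.to_numpy().tolist(),
            "loglik": float(self.llf),
            "k_params": int(self.k_params),
            "aic": float(self.criteria.aic),
            "bic": float(self.criteria.bic),
            "caic": float(self.criteria.caic),
        }


def class_sweep(panel, c_min: int = 2, c_max: int = 9, n_starts: int = 10,
                seed: int | None = None, reference: str | None = None,
                **fit_kwargs) -> pd.DataFrame:
    """Fit C = c_min..c_max classes and tabulate the selection criteria.

    Returns one row per class count with the log-likelihood, AIC/BIC/CAIC,
    and percent-improvement columns (Delta relative to the previous row).
    The leveling-off of the Delta columns indicates the class count to
    retain; no automatic selection is made.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for c, child in zip(range(c_min, c_max + 1), ss.spawn(c_max - c_min + 1)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            res = LatentClassMaxDiffModel(panel, c, reference=reference).fit(
                n_starts=n_starts, seed=child_seed, compute_se=False, **fit_kwargs)
            rows.append({"classes": c, "loglik": res.llf, "aic": res.criteria.aic,
                         "caic": res.criteria.caic, "bic": res.criteria.bic,
                         "error": ""})
        except RuntimeError as exc:  # propagate per-row, keep the table partial
            rows.append({"classes": c, "loglik": np.nan, "aic": np.nan,
                         "caic": np.nan, "bic": np.nan, "error": str(exc)})
    tab = pd.DataFrame(rows)
    for col in ("aic", "caic", "bic"):
        tab[f"delta_{col}_pct"] = delta_percent(tab[col].to_numpy())
    return tab[["classes", "loglik", "aic", "delta_aic_pct", "caic",
                "delta_caic_pct", "bic", "delta_bic_pct", "error"]]


def profile_classes(assignments: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Percent composition of each class per covariate level.

    For every covariate column, the distribution of levels within each class
    (column percentages summing to 100 per covariate block).  Respondents
    missing a covariate value are excluded pairwise; the returned frame
    carries the included counts in ``attrs['n_included']``.
    """
    cov = covariates.loc[covariates.index.intersection(assignments.index)]
    blocks = []
    n_included = {}
    for col in cov.columns:
        sub = cov[col].dropna()
        n_included[col] = int(len(sub))
        ct = pd.crosstab(sub, assignments.loc[sub.index], normalize="columns") * 100.0
        ct.index = pd.MultiIndex.from_product([[col], ct.index],
                                              names=["covariate", "level"])
        blocks.append(ct)
    out = pd.concat(blocks)
    out.attrs["n_included"] = n_included
    return out
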
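"""Synthetic best-worst panels with known data-generating processes.

Three DGP kinds mirror the estimators: ``pooled`` (one utility vector for
everyone), ``mixed`` (respondent utilities drawn from independent normals),
and ``latent_class`` (a finite mixture of utility vectors, optionally with
class-conditional categorical covariates).  For each respondent the latent
state is drawn once; each card's (best, worst) pair is then sampled from the
maxdiff pair probabilities.

Randomness is a single hierarchical stream (`numpy.random.SeedSequence`
spawned per respondent), so enlarging a panel never perturbs earlier
respondents' data and everything is reproducible by seed.

``study_fixture`` packages a seed-frozen panel emulating the published milk
study: 200 respondents, a (9, 9, 4) near-BIBD, the published 3-class
preference structure with shares (0.65, 0.21, 0.14), and class-dependent
household covariates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .design import BWDesign, generate_design
from .panel import ResponsePanel

__all__ = ["DGPSpec", "simulate_panel", "study_fixture", "load_study_fixture"]

_FIXTURE_DESIGN_SEED = 20170401  # survey field-work began April 2017
_FIXTURE_PANEL_SEED = 11


@dataclass
class DGPSpec:
    """Specification of a synthetic-panel data-generating process.

    ``params`` by kind:
      pooled:       {"beta": (v,)}
      mixed:        {"mu": (v,), "sigma": (v,)}  (sigma magnitudes are used)
      latent_class: {"class_beta": (C, v), "class_shares": (C,)}
    ``covariates``: optional {name: {"levels": [...], "probs": {class: [...]}}}
    (latent_class only).
    """

    kind: str
    design: BWDesign
    n_respondents: int
    params: dict
    covariates: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in {"pooled", "mixed", "latent_class"}:
            raise ValueError(f"unknown DGP kind {self.kind!r}")
        v = self.design.v
        if self.kind == "pooled":
            if len(np.asarray(self.params["beta"])) != v:
                raise ValueError("beta length must equal the item count")
        elif self.kind == "mixed":
            if len(np.asarray(self.params["mu"])) != v or \
                    len(np.asarray(self.params["sigma"])) != v:
                raise ValueError("mu and sigma must have length v")
        else:
            cb = np.atleast_2d(np.asarray(self.params["class_beta"], dtype=float))
            cs = np.asarray(self.params["class_shares"], dtype=float)
            if cb.shape[1] != v:
                raise ValueError("class_beta must have v columns")
            if len(cs) != cb.shape[0]:
                raise ValueError("one share per class required")
            if np.any(cs < 0) or abs(cs.sum() - 1.0) > 1e-9:
                raise ValueError("class_shares must lie on the simplex")


def _card_pair_cums(design: BWDesign, beta: np.ndarray):
    """Per block: (sorted shown, ordered pairs, cumulative pair probabilities)."""
    out = []
    for blk in design.blocks:
        shown = sorted(blk)
        u = beta[shown]
        diffs = u[:, None] - u[None, :]
        mask = ~np.eye(len(shown), dtype=bool)
        w = np.exp(diffs - diffs[mask].max())
        w = w[mask]  # row-major over i != j, matching expand_pairs order
        pairs = [(i, j) for i in shown for j in shown if i != j]
        out.append((pairs, np.cumsum(w / w.sum())))
    return out


def simulate_panel(spec: DGPSpec):
    """Simulate a complete panel from ``spec``.

    Returns ``(panel, truth)`` where ``truth`` seals the latent state used
    for every respondent: ``{"kind", "classes" or "beta_draws", ...}``.
    """
    design = spec.design
    v = design.v
    root = np.random.SeedSequence(spec.seed)
    resp_seeds = root.spawn(spec.n_respondents)

    records = []
    truth: dict = {"kind": spec.kind, "seed": spec.seed}
    cov_rows = []

    if spec.kind == "pooled":
        beta = np.asarray(spec.params["beta"], dtype=float)
        cache = {0: _card_pair_cums(design, beta)}
        truth["beta"] = beta
    elif spec.kind == "latent_class":
        class_beta = np.atleast_2d(np.asarray(spec.params["class_beta"], dtype=float))
        class_shares = np.asarray(spec.params["class_shares"], dtype=float)
        cache = {c: _card_pair_cums(design, class_beta[c])
                 for c in range(class_beta.shape[0])}
        truth["class_beta"] = class_beta
        truth["class_shares"] = class_shares
        truth["classes"] = np.empty(spec.n_respondents, dtype=int)
    else:
        mu = np.asarray(spec.params["mu"], dtype=float)
        sig = np.abs(np.asarray(spec.params["sigma"], dtype=float))
        truth["mu"], truth["sigma"] = mu, sig
        truth["beta_draws"] = np.empty((spec.n_respondents, v))

    width = len(str(max(spec.n_respondents, 1)))
    for n, ss in enumerate(resp_seeds):
        rng = np.random.default_rng(ss)
        rid = f"R{n + 1:0{width}d}"
        if spec.kind == "pooled":
            cards = cache[0]
        elif spec.kind == "latent_class":
            c = int(rng.choice(len(truth["class_shares"]), p=truth["class_shares"]))
            truth["classes"][n] = c
            cards = cache[c]
            if spec.covariates:
                row = {"respondent_id": rid}
                for name, cfg in spec.covariates.items():
                    p = np.asarray(cfg["probs"][f"class_{c + 1}"], dtype=float)
                    row[name] = cfg["levels"][int(rng.choice(len(p), p=p / p.sum()))]
                cov_rows.append(row)
        else:
            beta_n = truth["mu"] + truth["sigma"] * rng.standard_normal(v)
            truth["beta_draws"][n] = beta_n
            cards = _card_pair_cums(design, beta_n)
        u = rng.random(design.b)
        for card_id, (pairs, cum) in enumerate(cards):
            best, worst = pairs[int(np.searchsorted(cum, u[card_id]))]
            records.append((rid, card_id, best, worst))

    df = pd.DataFrame(records, columns=["respondent_id", "card_id", "best", "worst"])
    cov = None
    if cov_rows:
        cov = pd.DataFrame(cov_rows).set_index("respondent_id")
    panel = ResponsePanel(design, df, covariates=cov)
    return panel, truth


def study_fixture():
    """Regenerate the packaged study-scale fixture (deterministic).

    A (9, 9, 4) near-BIBD, a 200-respondent panel from the published 3-class
    preference structure, and class-dependent categorical covariates.
    Returns ``(design, panel, covariates)``; byte-identical to the files
    shipped under ``bwskit/data/``.
    """
    design = generate_design(9, 9, 4, seed=_FIXTURE_DESIGN_SEED)
    class_beta, class_shares = datasets.milk_study_class_solution()
    spec = DGPSpec(
        kind="latent_class",
        design=design,
        n_respondents=200,
        params={"class_beta": class_beta.to_numpy(), "class_shares": class_shares},
        covariates=datasets.milk_study_covariate_profiles(),
        seed=_FIXTURE_PANEL_SEED,
    )
    panel, _ = simulate_panel(spec)
    return design, panel, panel.covariates


def _data_path(name: str):
    return importlib.resources.files("bwskit") / "data" / name


def load_study_fixture():
    """Load the shipped fixture files (design, panel, covariates)."""
    from .panel import read_panel

    design = BWDesign.from_json(_data_path("fixture_design.json"))
    panel = read_panel(_data_path("fixture_panel.csv"), design,
                       covariates_path=_data_path("fixture_covariates.csv"))
    return design, panel, panel.covariates
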
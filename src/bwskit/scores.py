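"""Counting-based best-worst statistics.

Given per-option best (B) and worst (W) pick totals on a complete panel of
N respondents where option ``o`` appears on ``r_o`` cards, the module
computes:

* standardized best-worst score  (B - W) / (r_o * N), in [-1, 1];
* the positive ratio scale  sqrt(B / W);
* the standardized ratio scale  100 * sqrt(B/W) / max_o sqrt(B/W)
  (the top option anchors the scale at 100);
* relative importance  100 * sqrt(B/W) / sum_o sqrt(B/W), summing to 100%;
* the two weighting factors (100 over the max, and over the sum, of the
  square-root ratios), ranks, and per-respondent score dispersion.

Full precision is kept internally.  ``ScoreTable.display()`` reproduces the
published presentation convention: scores and square-root ratios shown to
2 decimals, and the relative-importance column (with its weighting factor)
recomputed from the 2-dp-rounded square-root ratios — the convention under
which the published milk-study table is internally consistent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "count_best_worst",
    "bw_score",
    "ratio_scores",
    "individual_scores",
    "ScoreTable",
    "score_panel",
]

ZERO_WORST_CORRECTION = 0.5  # continuity correction when W(o) = 0


def _round_half_away(x, decimals: int):
    """Round half away from zero (publication style, not banker's)."""
    scale = 10.0 ** decimals
    arr = np.asarray(x, dtype=float)
    rounded = np.sign(arr) * np.floor(np.abs(arr) * scale + 0.5) / scale
    if isinstance(x, pd.Series):
        return pd.Series(rounded, index=x.index)
    return rounded


def count_best_worst(panel) -> pd.DataFrame:
    """Per-option best and worst pick counts (columns ``best``, ``worst``)."""
    arr = panel.to_arrays()
    v = panel.design.v
    rows = np.arange(len(arr["best_pos"]))
    best_items = arr["shown"][rows, arr["best_pos"]]
    worst_items = arr["shown"][rows, arr["worst_pos"]]
    return pd.DataFrame(
        {
            "best": np.bincount(best_items, minlength=v),
            "worst": np.bincount(worst_items, minlength=v),
        },
        index=list(panel.design.items),
    )


def bw_score(best, worst, r, n):
    """Standardized best-worst score (B - W) / (r * N), bounded in [-1, 1]."""
    best = np.asarray(best, dtype=float)
    worst = np.asarray(worst, dtype=float)
    denom = np.asarray(r, dtype=float) * float(n)
    if np.any(denom <= 0):
        raise ValueError("r * N must be positive")
    return (best - worst) / denom


def ratio_scores(counts: pd.DataFrame) -> pd.DataFrame:
    """Square-root ratio scale and its standardizations from (B, W) counts.

    Options with W = 0 get the documented continuity correction
    (W replaced by 0.5) and are flagged in the ``zero_worst`` column.
    """
    best = counts["best"].to_numpy(dtype=float)
    worst = counts["worst"].to_numpy(dtype=float)
    zero = worst == 0
    if zero.any():
        warnings.warn(
            f"zero worst counts for {list(counts.index[zero])}; applying the "
            f"W={ZERO_WORST_CORRECTION} continuity correction", RuntimeWarning)
    wadj = np.where(zero, ZERO_WORST_CORRECTION, worst)
    sqrt_ratio = np.sqrt(best / wadj)
    smax = sqrt_ratio.max()
    ssum = sqrt_ratio.sum()
    out = pd.DataFrame(index=counts.index)
    out["sqrt_ratio"] = sqrt_ratio
    out["std_ratio"] = 100.0 * sqrt_ratio / smax
    out["rel_importance_pct"] = 100.0 * sqrt_ratio / ssum
    out["zero_worst"] = zero
    # rank 1 = highest relative importance; ties broken by option label order
    order = np.lexsort((np.arange(len(out)), -sqrt_ratio))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    out.attrs["weight_std_ratio"] = 100.0 / smax
    out.attrs["weight_rel_importance"] = 100.0 / ssum
    return out


def individual_scores(panel) -> pd.DataFrame:
    """Per-respondent standardized scores (B_n - W_n) / r_o per option.

    Row mean equals the aggregate best-worst score; the population standard
    deviation of each column is the dispersion printed alongside aggregate
    scores.
    """
    arr = panel.to_arrays()
    v = panel.design.v
    n = arr["n_respondents"]
    rows = np.arange(len(arr["best_pos"]))
    best_items = arr["shown"][rows, arr["best_pos"]]
    worst_items = arr["shown"][rows, arr["worst_pos"]]
    b = np.zeros((n, v))
    w = np.zeros((n, v))
    np.add.at(b, (arr["resp_idx"], best_items), 1.0)
    np.add.at(w, (arr["resp_idx"], worst_items), 1.0)
    r = panel.design.replication.astype(float)
    return pd.DataFrame((b - w) / r[None, :], index=arr["resp_ids"],
                        columns=list(panel.design.items))


class ScoreTable:
    """Full counting-score table, built from a panel or from raw counts."""

    def __init__(self, table: pd.DataFrame, weight_std_ratio: float,
                 weight_rel_importance: float, n_respondents: int,
                 individual: pd.DataFrame | None = None):
        self.table = table
        self.weight_std_ratio = weight_std_ratio
        self.weight_rel_importance = weight_rel_importance
        self.n_respondents = n_respondents
        self.individual = individual

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, r, n_respondents: int,
                    individual: pd.DataFrame | None = None) -> "ScoreTable":
        """Score table from per-option (best, worst) counts.

        ``r`` is the per-option appearance count across one respondent's
        cards (scalar or per-option).
        """
        r = pd.Series(np.broadcast_to(np.asarray(r), len(counts)),
                      index=counts.index)
        tab = counts.copy()
        tab["bw_score"] = bw_score(counts["best"], counts["worst"], r,
                                   n_respondents)
        if individual is not None:
            tab["individual_sd"] = individual.std(axis=0, ddof=0)
        ratios = ratio_scores(counts)
        table = pd.concat([tab, ratios], axis=1)
        return cls(table, ratios.attrs["weight_std_ratio"],
                   ratios.attrs["weight_rel_importance"], n_respondents,
                   individual)

    @classmethod
    def from_panel(cls, panel) -> "ScoreTable":
        if not panel.is_complete():
            raise ValueError("counting scores require a complete panel")
        counts = count_best_worst(panel)
        return cls.from_counts(counts, panel.design.replication,
                               panel.n_respondents,
                               individual=individual_scores(panel))

    def display(self) -> pd.DataFrame:
        """Publication-style rounding of the score table.

        Scores, dispersions and sqrt ratios to 2 dp; the standardized ratio
        scale to 2 dp at full precision; relative importance to 1 dp,
        recomputed from the 2-dp-rounded square-root ratios (the published
        convention).
        """
        t = self.table
        sq2 = _round_half_away(t["sqrt_ratio"], 2)
        rel = 100.0 * sq2 / sq2.sum()
        out = pd.DataFrame({
            "best": t["best"],
            "worst": t["worst"],
            "bw_score": _round_half_away(t["bw_score"], 2),
            "individual_sd": _round_half_away(t["individual_sd"], 4)
            if "individual_sd" in t else np.nan,
            "sqrt_ratio": sq2,
            "std_ratio": _round_half_away(t["std_ratio"], 2),
            "rel_importance_pct": _round_half_away(rel, 1),
            "rank": t["rank"],
        })
        out.attrs["weight_std_ratio"] = float(_round_half_away(self.weight_std_ratio, 2))
        out.attrs["weight_rel_importance"] = float(_round_half_away(100.0 / sq2.sum(), 2))
        return out


def score_panel(panel) -> ScoreTable:
    """Convenience constructor mirroring the estimator entry points."""
    return ScoreTable.from_panel(panel)
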
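"""Response panels for best-worst scaling experiments.

A *panel* records, for every respondent and every choice card (block of the
design), which shown option was picked as best (most likely) and which as
worst (least likely).  The maxdiff model treats each card as a single choice
among all ordered (best, worst) pairs of the shown options, so this module
also expands cards into their pair choice sets.

All file I/O is plain CSV:

* responses: columns ``respondent_id,card_id,best,worst`` with item labels;
* covariates: arbitrary categorical columns keyed by ``respondent_id``.

Canonical serialization sorts rows by (respondent, card) so that round trips
are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BWDesign

__all__ = ["ResponsePanel", "PairChoiceSet", "expand_pairs", "read_panel", "write_panel"]


@dataclass(frozen=True)
class PairChoiceSet:
    """All ordered (best-candidate, worst-candidate) pairs of one card."""

    shown: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]
    chosen: int  # index into ``pairs`` of the observed (best, worst) pair


def expand_pairs(shown, best=None, worst=None) -> PairChoiceSet:
    """Expand a card's shown set into its J(J-1) ordered pairs.

    Pairs are enumerated in deterministic lexicographic order over the sorted
    shown item indices.  When ``best``/``worst`` are given, the chosen pair
    index is resolved (and validated) as well.
    """
    shown = tuple(sorted(int(i) for i in shown))
    if len(shown) < 2:
        raise ValueError("a card needs at least two shown items")
    if len(set(shown)) != len(shown):
        raise ValueError("shown items must be distinct")
    pairs = tuple((i, j) for i in shown for j in shown if i != j)
    chosen = -1
    if best is not None or worst is not None:
        if best == worst:
            raise ValueError("best and worst must differ")
        try:
            chosen = pairs.index((int(best), int(worst)))
        except ValueError:
            raise ValueError("(best, worst) pair not in the card's shown set") from None
    return PairChoiceSet(shown=shown, pairs=pairs, chosen=chosen)


class ResponsePanel:
    """Validated best-worst responses of N respondents on a design.

    Parameters
    ----------
    design
        The card layout the responses refer to.
    responses
        DataFrame with columns ``respondent_id``, ``card_id`` (0-based block
        index), ``best``, ``worst`` (0-based item indices).
    covariates
        Optional per-respondent categorical table indexed by respondent id.
    allow_incomplete
        Accept respondents with missing cards.  Missing cards are simply
        absent rows (the maxdiff likelihood factorizes over cards); without
        the flag every respondent must answer every block exactly once.
    """

    def __init__(self, design: BWDesign, responses: pd.DataFrame,
                 covariates: pd.DataFrame | None = None,
                 allow_incomplete: bool = False):
        self.design = design
        df = responses[["respondent_id", "card_id", "best", "worst"]].copy()
        df["card_id"] = df["card_id"].astype(int)
        df["best"] = df["best"].astype(int)
        df["worst"] = df["worst"].astype(int)
        df = df.sort_values(["respondent_id", "card_id"], kind="stable")
        df = df.reset_index(drop=True)
        self._df = df
        self.covariates = covariates
        self.allow_incomplete = bool(allow_incomplete)
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        des = self.design
        df = self._df
        if df.empty:
            raise ValueError("empty panel")
        bad = df["card_id"].lt(0) | df["card_id"].ge(des.b)
        if bad.any():
            raise ValueError(f"card_id out of range in rows {df.index[bad].tolist()}")
        dup = df.duplicated(subset=["respondent_id", "card_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate card: respondent {row['respondent_id']!r} "
                f"card {int(row['card_id'])}"
            )
        for row in df.itertuples(index=False):
            blk = des.blocks[row.card_id]
            if row.best == row.worst:
                raise ValueError(
                    f"best equals worst for respondent {row.respondent_id!r} "
                    f"card {row.card_id}"
                )
            if row.best not in blk or row.worst not in blk:
                raise ValueError(
                    f"choice not among shown options for respondent "
                    f"{row.respondent_id!r} card {row.card_id}"
                )
        if not self.allow_incomplete:
            counts = df.groupby("respondent_id").size()
            if not (counts == des.b).all():
                bad_resp = counts.index[counts != des.b].tolist()
                raise ValueError(
                    f"incomplete panel (pass allow_incomplete=True to accept): "
                    f"respondents {bad_resp} do not answer all {des.b} cards"
                )

    # ------------------------------------------------------------------
    @property
    def respondents(self) -> list:
        return self._df["respondent_id"].unique().tolist()

    @property
    def n_respondents(self) -> int:
        return self._df["respondent_id"].nunique()

    @property
    def n_cards(self) -> int:
        return len(self._df)

    @property
    def frame(self) -> pd.DataFrame:
        """The response table (respondent_id, card_id, best, worst), 0-based."""
        return self._df.copy()

    def is_complete(self) -> bool:
        return bool((self._df.groupby("respondent_id").size() == self.design.b).all())

    def cards(self):
        """Iterate (respondent_id, card_id, shown, best, worst) records."""
        for row in self._df.itertuples(index=False):
            yield (row.respondent_id, row.card_id,
                   self.design.blocks[row.card_id], row.best, row.worst)

    def to_arrays(self) -> dict:
        """Dense arrays for the estimators.

        Returns resp_idx (n_obs, respondent codes 0..N-1), shown (n_obs, k),
        best_pos / worst_pos (position of the pick within the shown row),
        respondent id order, and item/respondent counts.
        """
        df = self._df
        resp_ids, resp_idx = np.unique(df["respondent_id"].to_numpy(), return_inverse=True)
        shown = np.array([self.design.blocks[c] for c in df["card_id"]], dtype=int)
        best = df["best"].to_numpy()
        worst = df["worst"].to_numpy()
        best_pos = (shown == best[:, None]).argmax(axis=1)
        worst_pos = (shown == worst[:, None]).argmax(axis=1)
        return {
            "resp_idx": resp_idx,
            "resp_ids": resp_ids,
            "shown": shown,
            "best_pos": best_pos,
            "worst_pos": worst_pos,
            "n_respondents": len(resp_ids),
            "n_items": self.design.v,
        }

    # ------------------------------------------------------------------
    def to_frame_labeled(self) -> pd.DataFrame:
        """Canonical labeled form used for CSV serialization."""
        des = self.design
        out = self._df.copy()
        out["best"] = [des.items[i] for i in out["best"]]
        out["worst"] = [des.items[i] for i in out["worst"]]
        return out

    def to_csv(self, path) -> None:
        self.to_frame_labeled().to_csv(path, index=False, lineterminator="\n")


def read_panel(path, design: BWDesign, covariates_path=None,
               allow_incomplete: bool = False) -> ResponsePanel:
    """Read a response CSV (respondent_id,card_id,best,worst) against a design.

    Labels are resolved through the design's item list; validation errors
    name the offending respondent and card.
    """
    df = pd.read_csv(path, dtype={"respondent_id": str})
    required = {"respondent_id", "card_id", "best", "worst"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response file missing columns: {sorted(missing)}")
    for col in ("best", "worst"):
        df[col] = [design.index_of(str(lab)) for lab in df[col]]
    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, dtype={"respondent_id": str})
        cov = cov.set_index("respondent_id")
    return ResponsePanel(design, df, covariates=cov, allow_incomplete=allow_incomplete)


def write_panel(panel: ResponsePanel, path, covariates_path=None) -> None:
    panel.to_csv(path)
    if covariates_path is not None and panel.covariates is not None:
        panel.covariates.to_csv(covariates_path, lineterminator="\n")
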
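"""Nearly balanced incomplete block designs (BIBDs) for best-worst choice cards.

A best-worst scaling experiment shows each respondent a series of *cards*
(blocks), each containing a subset of ``k`` of the ``v`` items under study.
A (near-)BIBD keeps every item equally replicated across the ``b`` cards and
makes pairwise co-occurrence counts as even as possible, so that every item
and every item contrast is observed with comparable precision.

This module constructs such designs by randomized greedy assignment followed
by pairwise item-exchange hill climbing on the variance of the off-diagonal
concurrence counts, and computes the standard balance diagnostics
(replication, concurrence, average pairwise frequency, D-efficiency of the
intra-block information matrix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BWDesign",
    "generate_design",
    "average_pairwise_frequency",
    "design_efficiency",
]

DESIGN_FORMAT_VERSION = 1


def _default_labels(v: int) -> list[str]:
    return [f"O{i + 1}" for i in range(v)]


@dataclass(frozen=True)
class BWDesign:
    """A block design: ``v`` items arranged in ``b`` blocks of size ``k``.

    Blocks are stored as sorted tuples of 0-based item indices; presentation
    order within a card is not modelled.  Item labels (``O1`` .. ``Ov`` by
    default) are used in all file I/O.
    """

    items: tuple[str, ...]
    blocks: tuple[tuple[int, ...], ...]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(
            self, "blocks", tuple(tuple(sorted(b)) for b in self.blocks)
        )
        v = self.v
        if len(set(self.items)) != v:
            raise ValueError("item labels must be unique")
        if not self.blocks:
            raise ValueError("design needs at least one block")
        k = len(self.blocks[0])
        for blk in self.blocks:
            if len(blk) != k or len(set(blk)) != k:
                raise ValueError("every block must have k distinct items")
            if min(blk) < 0 or max(blk) >= v:
                raise ValueError("block item index out of range")

    # -- basic dimensions -------------------------------------------------
    @property
    def v(self) -> int:
        return len(self.items)

    @property
    def b(self) -> int:
        return len(self.blocks)

    @property
    def k(self) -> int:
        return len(self.blocks[0])

    # -- derived structure ------------------------------------------------
    @property
    def incidence(self) -> np.ndarray:
        """v x b 0/1 incidence matrix N (items in rows, blocks in columns)."""
        if "incidence" not in self._cache:
            n = np.zeros((self.v, self.b), dtype=int)
            for j, blk in enumerate(self.blocks):
                n[list(blk), j] = 1
            self._cache["incidence"] = n
        return self._cache["incidence"]

    @property
    def replication(self) -> np.ndarray:
        """Per-item count r_i of blocks containing item i."""
        return self.incidence.sum(axis=1)

    @property
    def concurrence(self) -> np.ndarray:
        """v x v matrix of pairwise co-occurrence counts; diagonal = replication."""
        n = self.incidence
        return n @ n.T

    def label_of(self, index: int) -> str:
        return self.items[index]

    def index_of(self, label: str) -> int:
        try:
            return self.items.index(label)
        except ValueError:
            raise KeyError(f"unknown item label {label!r}") from None

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": DESIGN_FORMAT_VERSION,
            "v": self.v,
            "b": self.b,
            "k": self.k,
            "item_labels": list(self.items),
            "blocks": [[self.items[i] for i in blk] for blk in self.blocks],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "BWDesign":
        items = list(d["item_labels"])
        idx = {lab: i for i, lab in enumerate(items)}
        blocks = [tuple(idx[lab] for lab in blk) for blk in d["blocks"]]
        des = cls(items=tuple(items), blocks=tuple(blocks))
        for key in ("v", "b", "k"):
            if key in d and getattr(des, key) != d[key]:
                raise ValueError(f"design file inconsistent: {key}")
        return des

    @classmethod
    def from_json(cls, path) -> "BWDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _offdiag_pairs(conc: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(conc.shape[0], k=1)
    return conc[iu]


def _balance_cost(conc: np.ndarray) -> int:
    # variance of off-diagonal concurrences has a fixed mean given (v,b,k),
    # so minimizing sum of squares is equivalent and stays integer-exact
    lam = _offdiag_pairs(conc)
    return int(np.sum(lam * lam))


def _equal_replication_start(v: int, b: int, k: int, rng) -> list[set]:
    """Deal item copies into blocks so each block has k distinct items."""
    r = b * k // v
    for _ in range(200):
        pool = np.repeat(np.arange(v), r)
        rng.shuffle(pool)
        blocks = [set() for _ in range(b)]
        leftovers = []
        pos = 0
        for j in range(b):
            while len(blocks[j]) < k and pos < len(pool):
                item = pool[pos]
                pos += 1
                if item in blocks[j]:
                    leftovers.append(item)
                else:
                    blocks[j].add(item)
        # place leftovers by swapping with a block that can host them
        ok = True
        for item in leftovers:
            placed = False
            order = rng.permutation(b)
            for j in order:
                if item in blocks[j] or len(blocks[j]) >= k:
                    continue
                blocks[j].add(item)
                placed = True
                break
            if not placed:
                # swap: find blocks j (full, lacks item) and j2 (has room for y)
                for j in order:
                    if item in blocks[j]:
                        continue
                    for y in list(blocks[j]):
                        hosts = [
                            j2
                            for j2 in range(b)
                            if j2 != j and y not in blocks[j2] and len(blocks[j2]) < k
                        ]
                        if hosts:
                            j2 = hosts[0]
                            blocks[j].remove(y)
                            blocks[j].add(item)
                            blocks[j2].add(y)
                            placed = True
                            break
                    if placed:
                        break
            if not placed:
                ok = False
                break
        if ok and all(len(blk) == k for blk in blocks):
            return blocks
    raise RuntimeError("could not construct an equal-replication start")


def generate_design(
    v: int,
    b: int,
    k: int,
    seed: int = 0,
    max_iter: int = 20000,
    n_restarts: int = 40,
    items: list[str] | None = None,
) -> BWDesign:
    """Search for a (near-)balanced incomplete block design.

    Starts from a random equal-replication assignment and hill-climbs on
    pairwise item exchanges between blocks, minimizing the variance of the
    off-diagonal concurrence counts; the best of ``n_restarts`` restarts is
    returned.  Deterministic for a fixed ``seed``.

    Raises ``ValueError`` when ``b*k`` is not divisible by ``v`` (equal
    replication is then unattainable).
    """
    if not (v >= k >= 2):
        raise ValueError(f"need v >= k >= 2, got v={v}, k={k}")
    if (b * k) % v != 0:
        raise ValueError(
            f"infeasible design: b*k = {b * k} is not divisible by v = {v}, "
            "so equal replication cannot be achieved"
        )
    if items is not None and len(items) != v:
        raise ValueError("items must have length v")
    rng = np.random.default_rng(seed)

    best_blocks = None
    best_cost = None
    # perfect balance (all off-diagonal concurrences equal) bounds the cost
    n_pairs = v * (v - 1) // 2
    total = b * k * (k - 1) // 2
    lo, rem = divmod(total, n_pairs)
    ideal_cost = (n_pairs - rem) * lo * lo + rem * (lo + 1) * (lo + 1)

    for _ in range(n_restarts):
        blocks = _equal_replication_start(v, b, k, rng)
        conc = np.zeros((v, v), dtype=int)
        for blk in blocks:
            idx = list(blk)
            for a in idx:
                for c in idx:
                    conc[a, c] += 1
        cost = _balance_cost(conc)
        it = 0
        improved = True
        while improved and it < max_iter:
            improved = False
            order = rng.permutation(b)
            for j1 in order:
                for j2 in range(b):
                    if j1 == j2:
                        continue
                    only1 = list(blocks[j1] - blocks[j2])
                    only2 = list(blocks[j2] - blocks[j1])
                    for x in only1:
                        z1 = [z for z in only1 if z != x]
                        for y in only2:
                            it += 1
                            # swap x (j1) <-> y (j2); replication unchanged.
                            # pairs with items shared by both blocks cancel, so
                            # only items unique to one block move the cost:
                            # decrement lam by 1 adds -2*lam+1, increment +2*lam+1
                            z2 = [z for z in only2 if z != y]
                            delta = (
                                2 * sum(conc[y, z] - conc[x, z] for z in z1)
                                + 2 * sum(conc[x, z] - conc[y, z] for z in z2)
                                + 2 * (len(z1) + len(z2))
                            )
                            if delta < 0:
                                for z in z1:
                                    conc[x, z] -= 1
                                    conc[z, x] -= 1
                                    conc[y, z] += 1
                                    conc[z, y] += 1
                                for z in z2:
                                    conc[y, z] -= 1
                                    conc[z, y] -= 1
                                    conc[x, z] += 1
                                    conc[z, x] += 1
                                blocks[j1].remove(x)
                                blocks[j1].add(y)
                                blocks[j2].remove(y)
                                blocks[j2].add(x)
                                cost = cost + delta
                                improved = True
                                break
                        if improved:
                            break
                    if improved:
                        break
                if improved:
                    break
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_blocks = [frozenset(blk) for blk in blocks]
        if best_cost <= ideal_cost:
            break

    labels = tuple(items) if items is not None else tuple(_default_labels(v))
    return BWDesign(items=labels, blocks=tuple(tuple(sorted(blk)) for blk in best_blocks))


def average_pairwise_frequency(design: BWDesign) -> float:
    """Mean co-occurrence count over all unordered item pairs.

    Computed from the concurrence matrix; equals the closed form
    ``b*k*(k-1) / (v*(v-1))`` for any design.
    """
    lam = _offdiag_pairs(design.concurrence)
    return float(lam.mean())


def design_efficiency(design: BWDesign) -> float:
    """D-efficiency (percent) of the intra-block information matrix.

    With ``C = diag(r) - N N' / k``, efficiency is the geometric mean of the
    ``v-1`` nonzero eigenvalues of C relative to their perfect-BIBD bound
    ``v*lambda_bar/k`` where ``lambda_bar = r(k-1)/(v-1)``.  Equals 100
    exactly for a perfect BIBD; requires equal replication.
    """
    r = design.replication
    if not np.all(r == r[0]):
        raise ValueError("design efficiency is defined only for equal replication")
    v, k = design.v, design.k
    n = design.incidence
    c = np.diag(r.astype(float)) - (n @ n.T) / k
    eig = np.sort(np.linalg.eigvalsh(c))
    nonzero = eig[1:]  # C has a single structural zero (row sums vanish)
    if np.any(nonzero <= 1e-10):
        return 0.0
    lam_bar = r[0] * (k - 1) / (v - 1)
    bound = v * lam_bar / k
    geo = float(np.exp(np.mean(np.log(nonzero))))
    return 100.0 * geo / bound
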
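"""Weight-ordered agreement-score fusion of multiple binary irrigation products.

N co-registered binary products are ranked by an expert-assigned weight
order (product A most trusted).  Each cropland pixel's agreement vector —
which products call it irrigated — is mapped to an integer score in
0..2^N - 1 that orders pixels primarily by agreement level (how many
products agree) and secondarily by *which* products agree, higher-weighted
products counting for more.  The score field then drives the same
area-constrained threshold allocation as the greenness-index step.

Two score-table modes are provided for N = 5.  ``paper5`` is the
canonical published 32-entry table, embedded verbatim; its ordering
inside agreement level 3 does not follow the simple descending-
lexicographic rule that levels 2 and 4 obey, so it cannot be regenerated
from a single rule.  ``systematic`` is the clean generalization for any
N: vectors sorted by descending agreement level, then by descending
lexicographic order with the rank-1 product most significant.  The two
modes agree everywhere except within level 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .area_allocator import allocate_map
from .grid_model import Grid, GridError

__all__ = ["ScoreTable", "Product", "ProductStack", "build_score_table",
           "compute_scores", "fuse", "PAPER5_TABLE"]

SCORE_NODATA = -1

# Canonical five-product agreement table: score -> agreement vector (A..E).
PAPER5_TABLE: dict[str, int] = {
    "11111": 31,
    "11110": 30, "11101": 29, "11011": 28, "10111": 27, "01111": 26,
    "11100": 25, "11010": 24, "10110": 23, "01110": 22, "11001": 21,
    "10101": 20, "01101": 19, "10011": 18, "01011": 17, "00111": 16,
    "11000": 15, "10100": 14, "10010": 13, "10001": 12, "01100": 11,
    "01010": 10, "01001": 9, "00110": 8, "00101": 7, "00011": 6,
    "10000": 5, "01000": 4, "00100": 3, "00010": 2, "00001": 1,
    "00000": 0,
}


@dataclass
class ScoreTable:
    """Bijection from N-bit agreement vectors to integer scores 0..2^N - 1."""

    n_products: int
    mode: str
    scores: dict[tuple[int, ...], int]

    def score(self, vector: Sequence[int]) -> int:
        return self.scores[tuple(int(b) for b in vector)]

    def lookup_array(self) -> np.ndarray:
        """scores indexed by the vector read as a binary number (A = MSB)."""
        arr = np.empty(2 ** self.n_products, dtype=np.int16)
        for vec, s in self.scores.items():
            code = int("".join(map(str, vec)), 2)
            arr[code] = s
        return arr

    def to_rows(self):
        """(vector string, agreement level, score) rows, descending score."""
        rows = [("".join(map(str, v)), sum(v), s) for v, s in self.scores.items()]
        return sorted(rows, key=lambda r: -r[2])


def build_score_table(n_products: int, mode: str = "systematic") -> ScoreTable:
    """Construct the agreement score table for ``n_products`` ranked products.

    ``paper5`` (requires n_products = 5): the published canonical table.
    ``systematic``: vectors ordered by (agreement level desc, vector desc
    lexicographically with the rank-1 product most significant), scored
    2^N - 1 down to 0.  Both modes give any level-k vector a strictly
    higher score than any level-(k-1) vector.
    """
    if n_products < 2:
        raise ValueError("need at least two products to fuse")
    if mode == "paper5":
        if n_products != 5:
            raise ValueError("paper5 mode is defined for exactly five products")
        scores = {tuple(int(c) for c in bits): s for bits, s in PAPER5_TABLE.items()}
        return ScoreTable(5, "paper5", scores)
    if mode != "systematic":
        raise ValueError(f"unknown score-table mode {mode!r}")
    vectors = [
        tuple((code >> (n_products - 1 - i)) & 1 for i in range(n_products))
        for code in range(2 ** n_products)
    ]
    ordered = sorted(vectors, key=lambda v: (sum(v), v), reverse=True)
    scores = {v: 2 ** n_products - 1 - i for i, v in enumerate(ordered)}
    return ScoreTable(n_products, "systematic", scores)


@dataclass
class Product:
    name: str
    grid: Grid
    rank: int  # 1 = highest weight


@dataclass
class ProductStack:
    """Co-registered binary products in descending weight order."""

    products: list[Product] = field(default_factory=list)

    def __post_init__(self):
        ranks = sorted(p.rank for p in self.products)
        if ranks != list(range(1, len(self.products) + 1)):
            raise ValueError(f"product ranks must be 1..N unique, got {ranks}")
        self.products.sort(key=lambda p: p.rank)
        base = self.products[0].grid
        for p in self.products[1:]:
            if not base.same_lattice(p.grid):
                raise GridError(f"product {p.name!r} not co-registered")

    def __len__(self) -> int:
        return len(self.products)


def compute_scores(stack: ProductStack, mask: Grid, table: ScoreTable) -> Grid:
    """Per-pixel agreement score on cropland; nodata (-1) elsewhere.

    Products are binarized (any nonzero value counts as irrigated) before
    their agreement vector is read.
    """
    if len(stack) != table.n_products:
        raise ValueError(f"stack has {len(stack)} products, table expects {table.n_products}")
    base = stack.products[0].grid
    if not base.same_lattice(mask):
        raise GridError("product stack and cropland mask must share one lattice")
    n = len(stack)
    code = np.zeros(base.shape, dtype=np.int32)
    for i, p in enumerate(stack.products):
        bit = (p.grid.values != 0).astype(np.int32)
        code |= bit << (n - 1 - i)
    scores = table.lookup_array()[code].astype(np.int16)
    scores[~mask.values.astype(bool)] = SCORE_NODATA
    return Grid(scores, transform=base.transform, crs_tag=base.crs_tag, nodata=SCORE_NODATA)


def fuse(
    stack: ProductStack,
    mask: Grid,
    regions: Grid,
    targets: Mapping[int, float],
    pixel_area: float,
    table: ScoreTable,
):
    """Score the stack and downscale regional targets on the score field.

    Identical threshold, tie, and cap rules as the greenness-index
    allocation.  Returns (binary irrigation map, per-region traces).
    """
    score_grid = compute_scores(stack, mask, table)
    return allocate_map(score_grid, mask, regions, targets, pixel_area)
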
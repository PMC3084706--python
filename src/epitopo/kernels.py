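"""Division kernels: daughter-sidedness probability tables.

When an ``m``-sided (hence ``m``-vertexed) polygonal cell divides along a
straight cleavage line, each daughter inherits ``k`` of the mother's vertices
plus the two new vertices created where the cleavage line meets the cell
boundary, so a daughter that receives ``k`` vertices has ``j = k + 2`` sides
and its sister has ``m + 4 - j``.  A division kernel tabulates the probability
that a randomly chosen daughter of an ``m``-sided mother has ``j`` sides.

Two weighting schemes are supported:

``gpnp``
    ``min_daughter_sides - 2`` vertices are pre-placed on each side of the
    cleavage line and the remaining vertices are distributed independently
    with probability 1/2 each, giving a shifted symmetric binomial.  This is
    the weighting of the classic synchronous-division chain model.

``strict``
    All ``m`` vertices are distributed independently with probability 1/2
    each, and outcomes leaving a daughter with fewer than
    ``min_daughter_sides`` sides are discarded, renormalizing the remainder.
    This corresponds to a division axis chosen purely at random.

``min_daughter_sides`` is 4 in the baseline models, 3 when transient
three-sided cells are permitted, and 2 for the two-sided extension (strict
weights with no per-side vertex minimum, so nothing is discarded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["KernelVariant", "DivisionKernel", "build_kernel", "sample_split"]

_WEIGHTS = ("gpnp", "strict")


@dataclass(frozen=True)
class KernelVariant:
    """A (weighting scheme, minimum daughter sidedness) pair."""

    weights: str
    min_daughter_sides: int

    def __post_init__(self) -> None:
        if self.weights not in _WEIGHTS:
            raise ValueError(
                f"unknown weights {self.weights!r}; expected one of {_WEIGHTS}"
            )
        if self.min_daughter_sides not in (2, 3, 4):
            raise ValueError(
                f"min_daughter_sides must be 2, 3 or 4, got {self.min_daughter_sides}"
            )
        if self.weights == "gpnp" and self.min_daughter_sides == 2:
            # With no pre-placed vertices the two schemes coincide; the
            # two-sided extension is defined through strict weights.
            raise ValueError(
                "the 2-sided variant is defined with strict weights "
                "(use KernelVariant('strict', 2))"
            )

    @property
    def min_divisible_mother(self) -> int:
        """Smallest mother sidedness with at least one legal split."""
        return max(2 * self.min_daughter_sides - 4, 2)


def _row(variant: KernelVariant, m: int) -> tuple[int, np.ndarray]:
    """Exact daughter-sidedness row for an ``m``-sided mother.

    Returns ``(j_min, probs)`` where ``probs[i]`` is the probability of a
    daughter having ``j_min + i`` sides.  Computed with integer
    combinatorics, so rows are exact up to one float division.
    """
    q = variant.min_daughter_sides
    j_min, j_max = q, m + 4 - q
    if variant.weights == "gpnp":
        # q-2 vertices pre-placed per side; f = m - 2(q-2) free vertices.
        f = m - 2 * (q - 2)
        weights = [math.comb(f, j - j_min) for j in range(j_min, j_max + 1)]
    else:
        # All m vertices i.i.d.; daughter keeps k = j - 2 of them.
        weights = [math.comb(m, j - 2) for j in range(j_min, j_max + 1)]
    total = sum(weights)
    return j_min, np.asarray(weights, dtype=float) / total


@dataclass(frozen=True)
class DivisionKernel:
    """Daughter-sidedness table for mothers up to ``m_max`` sides."""

    variant: KernelVariant
    m_max: int
    table: dict[int, tuple[int, np.ndarray]] = field(repr=False)

    def prob(self, m: int, j: int) -> float:
        """P(a random daughter of an m-sided mother has j sides)."""
        j_min, probs = self.row(m)
        if j < j_min or j >= j_min + len(probs):
            return 0.0
        return float(probs[j - j_min])

    def row(self, m: int) -> tuple[int, np.ndarray]:
        if m not in self.table:
            raise ValueError(
                f"mother sidedness {m} not divisible under {self.variant} "
                f"(divisible range is "
                f"[{self.variant.min_divisible_mother}, {self.m_max}])"
            )
        return self.table[m]

    def divisible(self, m: int) -> bool:
        return m in self.table

    def daughter_matrix(self, s_max: int) -> np.ndarray:
        """Dense matrix ``K[j, m]`` = P(daughter j | mother m), shape (s_max+1,)*2.

        Columns for non-divisible mothers are zero.
        """
        if s_max > self.m_max:
            raise ValueError(f"s_max={s_max} exceeds kernel m_max={self.m_max}")
        K = np.zeros((s_max + 1, s_max + 1))
        for m, (j_min, probs) in self.table.items():
            if m > s_max:
                continue
            hi = min(len(probs), s_max + 1 - j_min)
            K[j_min : j_min + hi, m] = probs[:hi]
        return K

    def to_frame(self):
        """Long-format table (variant, m, j, probability) for inspection."""
        import pandas as pd

        rows = []
        for m in sorted(self.table):
            j_min, probs = self.table[m]
            for i, p in enumerate(probs):
                rows.append(
                    {
                        "variant": f"{self.variant.weights}-{self.variant.min_daughter_sides}",
                        "m": m,
                        "j": j_min + i,
                        "probability": p,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_kernel(variant: KernelVariant, m_max: int = 64) -> DivisionKernel:
    """Tabulate daughter-sidedness rows for all divisible mothers up to m_max."""
    if not isinstance(variant, KernelVariant):
        variant = KernelVariant(*variant)
    m_lo = variant.min_divisible_mother
    if m_max < m_lo:
        raise ValueError(
            f"m_max={m_max} is below the smallest divisible mother "
            f"sidedness {m_lo} for {variant}"
        )
    table = {m: _row(variant, m) for m in range(m_lo, m_max + 1)}
    return DivisionKernel(variant=variant, m_max=m_max, table=table)


def sample_split(
    kernel: DivisionKernel, m: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw the sidedness pair (j1, j2) of the daughters of an m-sided mother.

    j1 follows the kernel row; j2 = m + 4 - j1 is its sister.
    """
    j_min, probs = kernel.row(m)
    j1 = j_min + int(rng.choice(len(probs), p=probs))
    return j1, m + 4 - j1
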
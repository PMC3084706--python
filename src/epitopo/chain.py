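"""Synchronous-generation Markov chain on cell-sidedness fractions.

Every cell divides once per generation.  One generation is the composition of
two linear maps acting on the vector of sidedness fractions:

1. the division step, replacing each m-sided mother fraction by its
   daughter-sidedness mixture (the kernel row; populations double but the
   model tracks fractions, which are unchanged by the doubling), and
2. the mean-field shift, giving every cell one extra side — the stand-in for
   the two neighbors of each dividing cell gaining a side, which averages to
   one extra side per cell per generation.

The mean sidedness contracts toward the planar-tissue value 6 with factor
exactly 1/2 per generation (<s> -> <s>/2 + 3), and iterating the map reaches
a steady state that depends only on the division kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import SidednessDistribution
from .kernels import DivisionKernel

__all__ = [
    "generation_map",
    "division_step",
    "steady_state",
    "mean_sidedness",
    "SteadyStateResult",
]

_MASS_TOL = 1e-12


def _check_support(p: SidednessDistribution, kernel: DivisionKernel) -> None:
    if p.s_max > kernel.m_max and p.tail_mass(kernel.m_max + 1) > _MASS_TOL:
        raise ValueError(
            f"distribution support exceeds kernel m_max={kernel.m_max}"
        )
    m_lo = kernel.variant.min_divisible_mother
    if float(p.probs[:m_lo].sum()) > _MASS_TOL:
        raise ValueError(
            f"distribution has mass on mothers below the divisible minimum "
            f"{m_lo} for {kernel.variant}"
        )


def division_step(
    p: SidednessDistribution, kernel: DivisionKernel
) -> SidednessDistribution:
    """Intermediate (post-division, pre-shift) state of one generation.

    This is where transient 3-sided (or 2-sided) daughters live under the
    relaxed kernels; the shift converts them to 4-/5-sided cells before the
    generation closes.
    """
    _check_support(p, kernel)
    # daughters of an m-sided mother reach m + 4 - min_daughter_sides sides
    out = np.zeros(p.s_max + 3)
    for m in range(kernel.variant.min_divisible_mother, p.s_max + 1):
        pm = p.probs[m]
        if pm <= 0:
            continue
        j_min, row = kernel.row(m)
        out[j_min : j_min + len(row)] += pm * row
    return SidednessDistribution(out)


def generation_map(
    p: SidednessDistribution, kernel: DivisionKernel
) -> SidednessDistribution:
    """One full generation: division step followed by the +1-side shift."""
    q = division_step(p, kernel).probs
    shifted = np.zeros(len(q) + 1)
    shifted[1:] = q
    return SidednessDistribution(shifted)


def mean_sidedness(p: SidednessDistribution) -> float:
    return p.mean()


@dataclass(frozen=True)
class SteadyStateResult:
    distribution: SidednessDistribution
    iterations: int
    residual: float


def steady_state(
    kernel: DivisionKernel,
    p0: SidednessDistribution | None = None,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    s_max: int = 64,
) -> SteadyStateResult:
    """Iterate the generation map to its fixed point.

    The fixed point is independent of ``p0`` (default: all cells 6-sided).
    Mass trying to leave the truncation window ``s_max`` raises rather than
    being clipped; at the steady state the tail is far below ``tol`` for the
    default window.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if p0 is None:
        p0 = SidednessDistribution.delta(6)
    p = SidednessDistribution(p0.padded(s_max))
    for it in range(1, max_iter + 1):
        q = generation_map(p, kernel)
        spill = float(q.probs[s_max + 1 :].sum())
        if spill > 1e-13:
            raise ValueError(
                f"mass {spill:.2e} attempted to exceed the truncation window "
                f"s_max={s_max}; increase s_max"
            )
        q = SidednessDistribution(q.probs[: s_max + 1])
        residual = float(np.abs(q.probs - p.probs).sum())
        p = q
        if residual < tol:
            return SteadyStateResult(p, it, residual)
    raise RuntimeError(
        f"no convergence within {max_iter} generations (L1 residual {residual:.3e})"
    )
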
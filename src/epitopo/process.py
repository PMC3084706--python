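"""Asynchronous cell-division Markov process, simulated exactly with Gillespie.

Each cell divides at a constant rate λ (a pure time scale).  A division event
is an atomic block: an m-sided mother, chosen uniformly per cell among the
divisible classes, is replaced by daughters with j and m+4−j sides drawn from
a division kernel; then two side-recipient cells are chosen uniformly per
cell from the post-division population and each gains one side.  Every event
therefore adds exactly one cell and six sides, so a population initialized
with all-6-sided cells keeps mean sidedness exactly 6 in every realization.

Only per-class counts are tracked, so memory is O(s_max) and populations of
millions of cells are simulated in seconds (the inner loop is numba-compiled).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .distributions import SidednessDistribution
from .kernels import DivisionKernel, build_kernel

__all__ = [
    "PopulationState",
    "init_population",
    "gillespie_step",
    "run_to_population",
    "histogram",
]


@dataclass(frozen=True)
class PopulationState:
    counts: np.ndarray = field(repr=False)  # int64, indexed by sidedness
    time: float = 0.0
    lam: float = 1.0

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def total_sides(self) -> int:
        return int(np.arange(len(self.counts)) @ self.counts)

    def as_dict(self) -> dict[int, int]:
        sup = np.nonzero(self.counts)[0]
        return {int(s): int(self.counts[s]) for s in sup}


def init_population(n0: int, s0: int = 6, lam: float = 1.0,
                    s_cap: int = 192) -> PopulationState:
    """All-``s0``-sided population of ``n0`` cells at time zero."""
    if n0 < 2:
        raise ValueError("need at least two cells")
    if not 2 <= s0 < s_cap - 4:
        raise ValueError(f"s0={s0} outside the tracked sidedness range")
    counts = np.zeros(s_cap, dtype=np.int64)
    counts[s0] = n0
    return PopulationState(counts=counts, lam=lam)


def _kernel_rows(kernel: DivisionKernel, s_cap: int) -> np.ndarray:
    """Dense P[m, j] over the tracked range; daughters must fit in s_cap."""
    P = np.zeros((s_cap, s_cap))
    for m, (j_min, probs) in kernel.table.items():
        if m + 4 >= s_cap:
            break
        P[m, j_min : j_min + len(probs)] = probs
    return P


def _pick_class(counts: np.ndarray, u: float, start: int = 0) -> int:
    acc = 0.0
    for s in range(start, len(counts)):
        acc += counts[s]
        if u < acc:
            return s
    return int(np.nonzero(counts)[0][-1])


def gillespie_step(
    state: PopulationState,
    kernel: DivisionKernel,
    rng: np.random.Generator,
    distinct_recipients: bool = False,
) -> PopulationState:
    """One division event (pure-python reference path; used for small systems)."""
    counts = state.counts.copy()
    m_lo = kernel.variant.min_divisible_mother
    n_div = int(counts[m_lo:].sum())
    if state.n == 0:
        raise ValueError("empty population")
    if n_div == 0:
        raise ValueError("no divisible cells")
    dt = rng.exponential(1.0 / (state.lam * n_div))

    m = _pick_class(counts, rng.random() * n_div, start=m_lo)
    if m + 4 >= len(counts):
        raise RuntimeError("sidedness range exceeded; increase s_cap")
    j_min, probs = kernel.row(m)
    j1 = j_min + int(rng.choice(len(probs), p=probs))
    j2 = m + 4 - j1
    counts[m] -= 1
    counts[j1] += 1
    counts[j2] += 1

    n = state.n + 1
    s1 = _pick_class(counts, rng.random() * n)
    counts[s1] -= 1
    counts[s1 + 1] += 1
    if distinct_recipients:
        # exclude the first recipient (now in class s1+1) from the second draw
        w = rng.random() * (n - 1)
        excl = counts.copy()
        excl[s1 + 1] -= 1
        s2 = _pick_class(excl, w)
    else:
        s2 = _pick_class(counts, rng.random() * n)
    counts[s2] -= 1
    counts[s2 + 1] += 1
    if counts.min() < 0:
        raise AssertionError("negative class count")
    return replace(state, counts=counts, time=state.time + dt)


@njit(cache=True)
def _run_core(counts, P, m_lo, lam, target_n, seed, distinct):  # pragma: no cover
    np.random.seed(seed)
    L = counts.shape[0]
    n = 0
    n_div = 0
    for s in range(L):
        n += counts[s]
        if s >= m_lo:
            n_div += counts[s]
    t = 0.0
    while n < target_n:
        if n_div == 0:
            return t, 1  # stuck: no divisible cells
        t += np.random.exponential(1.0 / (lam * n_div))

        # mother, uniform per cell over divisible classes
        u = np.random.random() * n_div
        acc = 0.0
        m = -1
        for s in range(m_lo, L):
            acc += counts[s]
            if u < acc:
                m = s
                break
        if m < 0 or m + 5 >= L:
            return t, 2  # sidedness range exceeded
        counts[m] -= 1
        n_div -= 1

        # daughters from the kernel row
        v = np.random.random()
        accp = 0.0
        j1 = m + 4 - m_lo  # guard against rounding at the row end
        for j in range(L):
            if P[m, j] > 0.0:
                accp += P[m, j]
                if v < accp:
                    j1 = j
                    break
        j2 = m + 4 - j1
        counts[j1] += 1
        counts[j2] += 1
        n += 1
        if j1 >= m_lo:
            n_div += 1
        if j2 >= m_lo:
            n_div += 1

        # two side recipients, uniform per cell, sequential draws
        prev = -1
        for r in range(2):
            if distinct and r == 1:
                w = np.random.random() * (n - 1)
                acc2 = 0.0
                sr = -1
                for s in range(L):
                    c = counts[s]
                    if s == prev:
                        c -= 1
                    acc2 += c
                    if w < acc2:
                        sr = s
                        break
            else:
                w = np.random.random() * n
                acc2 = 0.0
                sr = -1
                for s in range(L):
                    acc2 += counts[s]
                    if w < acc2:
                        sr = s
                        break
            if sr < 0 or sr + 1 >= L:
                return t, 2
            counts[sr] -= 1
            counts[sr + 1] += 1
            if sr + 1 == m_lo:
                n_div += 1
            prev = sr + 1
    return t, 0


def run_to_population(
    state: PopulationState,
    kernel: DivisionKernel,
    target_n: int,
    rng: np.random.Generator,
    distinct_recipients: bool = False,
) -> PopulationState:
    """Run division events until the population reaches ``target_n`` cells."""
    if target_n <= state.n:
        raise ValueError("target_n must exceed the current population")
    counts = state.counts.astype(np.int64).copy()
    P = _kernel_rows(kernel, len(counts))
    seed = int(rng.integers(1 << 31))
    t, err = _run_core(
        counts, P, kernel.variant.min_divisible_mother, state.lam,
        target_n, seed, distinct_recipients,
    )
    if err == 1:
        raise RuntimeError("population has no divisible cells")
    if err == 2:
        raise RuntimeError(
            "sidedness exceeded the tracked range; re-initialize with a larger s_cap"
        )
    return replace(state, counts=counts, time=state.time + t)


def histogram(state: PopulationState) -> SidednessDistribution:
    """Relative class fractions N_s / N of the current population."""
    return SidednessDistribution.from_counts(state.counts)


def quasi_steady_state_histogram(
    variant,
    n0: int = 1000,
    target_n: int = 1_000_000,
    seed: int | np.random.Generator = 0,
    distinct_recipients: bool = False,
) -> SidednessDistribution:
    """Convenience front-end: grow an all-6 population and read the histogram."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kernel = build_kernel(variant, m_max=192)
    state = init_population(n0, 6)
    state = run_to_population(state, kernel, target_n, rng,
                              distinct_recipients=distinct_recipients)
    return histogram(state)
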
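"""Shared fixtures and independent oracles.

The grown sheet is expensive (about two minutes) and session-scoped: one
desk-scale tissue is grown once and shared by all tests that interrogate a
confluent configuration.
"""

from itertools import product

import numpy as np
import pytest

from epitopo import scem
from epitopo.kernels import KernelVariant

DESK_SEED = 20260922

CHAIN_VARIANTS = [
    KernelVariant("gpnp", 4),
    KernelVariant("gpnp", 3),
    KernelVariant("strict", 4),
    KernelVariant("strict", 3),
]
ALL_VARIANTS = CHAIN_VARIANTS + [KernelVariant("strict", 2)]


@pytest.fixture(scope="session")
def grown_sheet():
    """Desk-scale tissue: 37 seed cells of 32 elements grown to 150 cells."""
    rng = np.random.default_rng(DESK_SEED)
    growth = scem.GrowthParams(n0=32, alpha=0.55, p_rep=0.01)
    sheet = scem.seed_sheet(37, growth, rng=rng)
    scem.run_growth(sheet, 150, rng)
    return sheet


def brute_force_row(variant: KernelVariant, m: int) -> dict[int, float]:
    """Daughter-sidedness row by exhaustive enumeration of vertex placements.

    Independent of the package's combinatorial construction: every placement
    of the freely distributed vertices is enumerated as a left/right string.
    """
    q = variant.min_daughter_sides
    counts: dict[int, int] = {}
    if variant.weights == "gpnp":
        f = m - 2 * (q - 2)  # q-2 vertices pre-placed on each side
        for placement in product((0, 1), repeat=f):
            j = q + sum(placement)
            counts[j] = counts.get(j, 0) + 1
    else:
        for placement in product((0, 1), repeat=m):
            k = sum(placement)
            if k < q - 2 or m - k < q - 2:
                continue  # a daughter would fall below the minimum
            j = k + 2
            counts[j] = counts.get(j, 0) + 1
    total = sum(counts.values())
    return {j: c / total for j, c in counts.items()}


def enumerate_final_states(start: dict[int, int], kernel, target_n: int,
                           distinct: bool = False) -> dict[tuple, float]:
    """Exact distribution over final count-vectors of the division process.

    Recursively expands every possible event (mother class, daughter split,
    two sequential side recipients) with its probability.  Feasible for a
    handful of events; serves as the independent oracle for the Gillespie
    sampler.
    """
    m_lo = kernel.variant.min_divisible_mother
    out: dict[tuple, float] = {}

    def key(c):
        return tuple(sorted((s, n) for s, n in c.items() if n))

    def rec(c: dict[int, int], prob: float):
        n = sum(c.values())
        if n == target_n:
            out[key(c)] = out.get(key(c), 0.0) + prob
            return
        n_div = sum(v for s, v in c.items() if s >= m_lo)
        for m, nm in list(c.items()):
            if nm == 0 or m < m_lo:
                continue
            p_m = nm / n_div
            j_min, probs = kernel.row(m)
            for i, pj in enumerate(probs):
                if pj == 0:
                    continue
                j1, j2 = j_min + i, m + 4 - (j_min + i)
                c1 = dict(c)
                c1[m] -= 1
                c1[j1] = c1.get(j1, 0) + 1
                c1[j2] = c1.get(j2, 0) + 1
                n1 = n + 1
                for s1, ns1 in list(c1.items()):
                    if ns1 == 0:
                        continue
                    p1 = ns1 / n1
                    c2 = dict(c1)
                    c2[s1] -= 1
                    c2[s1 + 1] = c2.get(s1 + 1, 0) + 1
                    for s2, ns2 in list(c2.items()):
                        if ns2 == 0:
                            continue
                        if distinct and s2 == s1 + 1:
                            w = (ns2 - 1) / (n1 - 1)
                        elif distinct:
                            w = ns2 / (n1 - 1)
                        else:
                            w = ns2 / n1
                        if w == 0:
                            continue
                        c3 = dict(c2)
                        c3[s2] -= 1
                        c3[s2 + 1] = c3.get(s2 + 1, 0) + 1
                        rec(c3, prob * p_m * pj * p1 * w)

    rec({s: n for s, n in start.items() if n}, 1.0)
    return out
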
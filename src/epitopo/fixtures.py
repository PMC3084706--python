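"""Synthetic sheets with exactly known topology, for testing neighbor counting.

The hexagonal fixture partitions one global triangular element lattice
(spacing d0) into congruent centered-hexagonal patches, one per cell.  The
patches tile the lattice exactly, so every cross-boundary element pair sits
at exactly d0 and, at zero jitter, every interior cell has exactly six
neighbors for any contact cutoff δ in [1.0, √3).  Because the patches are
centered hexagonal numbers, the requested elements-per-cell is rounded up to
the nearest value in 1, 7, 19, 37, 61, ...
"""

from __future__ import annotations

import math

import numpy as np

from .scem import GrowthParams, PotentialParams, Sheet, _hex_ring_offsets

__all__ = ["hex_sheet_fixture", "centered_hex_number"]


def centered_hex_number(k: int) -> int:
    return 1 + 3 * k * (k + 1)


def hex_sheet_fixture(
    n_rings: int,
    n0: int = 37,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
    d0: float = 1.0,
    params: PotentialParams | None = None,
) -> Sheet:
    """Sheet of 1 + 3·n_rings·(n_rings+1) hexagonal cells with exact topology.

    ``n0`` is rounded up to a centered hexagonal number (see module note);
    ``jitter`` (units of d0, in [0, 0.3)) displaces each element uniformly in
    a disc of that radius.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be at least 1")
    if not 0 <= jitter < 0.3:
        raise ValueError("jitter must lie in [0, 0.3) (units of d0)")
    k = 0
    while centered_hex_number(k) < n0:
        k += 1
    n_el = centered_hex_number(k)

    # integer lattice: point (i, j) -> (i + j/2, j*sqrt(3)/2) * d0
    patch = _hex_ring_offsets(k)                       # (n_el, 2) ints
    # superlattice generated by the Eisenstein unit (k+1) + k*w: its norm
    # 3k^2+3k+1 equals the patch size, so translated patches tile exactly
    u1 = np.array([k + 1, k])
    u2 = np.array([-k, 2 * k + 1])
    centers = _hex_ring_offsets(n_rings) @ np.vstack([u1, u2])

    basis = np.array([[1.0, 0.0], [0.5, math.sqrt(3) / 2]]) * d0
    pos_blocks, cells = [], []
    for cid, c in enumerate(centers):
        pos_blocks.append((patch + c) @ basis)
        cells.append(np.full(n_el, cid, dtype=np.int64))
    pos = np.vstack(pos_blocks)
    if jitter > 0:
        rng = rng or np.random.default_rng()
        r = jitter * d0 * np.sqrt(rng.random(len(pos)))
        th = rng.uniform(0, 2 * math.pi, len(pos))
        pos = pos + np.column_stack([r * np.cos(th), r * np.sin(th)])
    return Sheet(
        pos=np.ascontiguousarray(pos),
        cell_of=np.concatenate(cells),
        params=params or PotentialParams(d0=d0),
        growth=GrowthParams(n0=n_el),
        next_cell_id=len(centers),
    )
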
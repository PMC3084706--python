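"""2D subcellular-element epithelium simulator.

Each cell is a cluster of ~n0 elements coupled by short-range pair
potentials (stronger within a cell than between cells) under overdamped
dynamics.  A cell grows by stochastic replication of core elements: a
candidate point is proposed a distance d0/2 from a core element in a random
direction and accepted only if it clears every other element by more than
α·d0 — raising α makes placement more space-sensitive and slows
proliferation.  Once a cell doubles its element count it splits evenly along
the line perpendicular to its geometric long axis (principal component of
its element positions).  Growth is adiabatic: replication is rare on the
mechanical relaxation time scale, so element density stays uniform.

Simulation units: d0 = 1 (element diameter), damping γ = 1, well depth = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import _mechanics as mech

__all__ = [
    "PotentialParams",
    "GrowthParams",
    "DivisionEvent",
    "Sheet",
    "seed_sheet",
    "step_dynamics",
    "attempt_growth",
    "divide_cell",
    "run_growth",
    "total_energy",
    "cell_aspect_ratios",
]


@dataclass(frozen=True)
class PotentialParams:
    """Tapered-Morse pair interaction and overdamped-dynamics scales."""

    d0: float = 1.0
    well_depth: float = 1.0
    decay_range: float = 0.25   # Morse decay length, units of d0
    cutoff: float = 2.0         # units of d0
    taper_start: float = 1.6    # units of d0; force -> 0 smoothly by cutoff
    intra_scale: float = 1.0
    inter_scale: float = 0.5
    damping: float = 1.0
    noise_amp: float = 0.0

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.well_depth > 0 and self.decay_range > 0):
            raise ValueError("d0, well_depth and decay_range must be positive")
        if not 1.0 < self.taper_start < self.cutoff:
            raise ValueError("need d0 < taper_start < cutoff (in units of d0)")

    @property
    def relaxation_time(self) -> float:
        """γ / U''(d0): the element-scale mechanical relaxation time."""
        k = 2.0 * self.well_depth / (self.decay_range * self.d0) ** 2
        return self.damping / k

    @property
    def stable_dt(self) -> float:
        """Conservative integrator bound (half the relaxation time)."""
        return 0.5 * self.relaxation_time


@dataclass(frozen=True)
class GrowthParams:
    n0: int = 128               # elements per newborn cell
    p_rep: float = 0.01         # replication probability per core element per sweep
    alpha: float = 0.55         # clearance threshold, units of d0
    core_fraction: float = 0.5  # innermost fraction eligible to replicate
    placement_distance: float = 0.5  # candidate offset from parent, units of d0

    def __post_init__(self) -> None:
        if not 0.5 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0.5, 1.0), got {self.alpha}")
        if not 0 < self.p_rep <= 1:
            raise ValueError("p_rep must be in (0, 1]")
        if not 0 < self.core_fraction <= 1:
            raise ValueError("core_fraction must be in (0, 1]")
        if self.n0 < 2:
            raise ValueError("n0 must be at least 2")


@dataclass(frozen=True)
class DivisionEvent:
    time: float
    mother: int
    daughter1: int
    daughter2: int
    axis_angle: float  # cleavage-line orientation, mod pi


@dataclass
class Sheet:
    """Off-lattice element configuration grouped into cells."""

    pos: np.ndarray                 # (N, 2) float64
    cell_of: np.ndarray             # (N,) int64
    params: PotentialParams
    growth: GrowthParams
    time: float = 0.0
    next_cell_id: int = 0
    division_log: list[DivisionEvent] = field(default_factory=list)

    @property
    def n_elements(self) -> int:
        return len(self.pos)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.unique(self.cell_of)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.cell_of, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def elements_of(self, cell_id: int) -> np.ndarray:
        return self.pos[self.cell_of == cell_id]

    def centroid(self, cell_id: int) -> np.ndarray:
        return self.elements_of(cell_id).mean(axis=0)


def _disc_positions(n: int, d0: float, rng: np.random.Generator,
                    jitter: float = 0.05) -> np.ndarray:
    """Sunflower (Fermat-spiral) packing of n elements at ~d0 spacing."""
    area_per_el = (math.sqrt(3) / 2) * d0 * d0
    R = math.sqrt(n * area_per_el / math.pi)
    golden = math.pi * (3 - math.sqrt(5))
    i = np.arange(n)
    r = R * np.sqrt((i + 0.5) / n)
    th = i * golden
    xy = np.column_stack([r * np.cos(th), r * np.sin(th)])
    if jitter > 0:
        xy += rng.normal(scale=jitter * d0, size=xy.shape)
    return xy


def _hex_ring_offsets(n_rings: int) -> np.ndarray:
    """Integer axial coordinates of a hex-lattice patch, center first."""
    out = [(0, 0)]
    for k in range(1, n_rings + 1):
        a, b = k, 0
        for da, db in ((-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)):
            for _ in range(k):
                out.append((a, b))
                a += da
                b += db
    return np.array(out)


def seed_sheet(
    n_cells: int,
    growth: GrowthParams,
    params: PotentialParams | None = None,
    rng: np.random.Generator | None = None,
    relax_steps: int = 200,
    dt: float | None = None,
) -> Sheet:
    """Hexagonal array of round n0-element cells, relaxed before growth.

    Cell centers fill hexagonal rings around the origin (37 cells = 3 rings,
    the standard seeding); each cell is a jittered sunflower disc packing.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    params = params or PotentialParams()
    rng = rng or np.random.default_rng()
    d0 = params.d0
    n_rings = 0
    while 1 + 3 * n_rings * (n_rings + 1) < n_cells:
        n_rings += 1
    v1 = np.array([1.0, 0.0])
    v2 = np.array([0.5, math.sqrt(3) / 2])
    L = math.sqrt(growth.n0) * d0  # confluent hexagonal tiling pitch
    centers = _hex_ring_offsets(n_rings)[:n_cells] @ np.vstack([v1, v2]) * L

    pos_blocks, cells = [], []
    for cid, c in enumerate(centers):
        pos_blocks.append(c + _disc_positions(growth.n0, d0, rng))
        cells.append(np.full(growth.n0, cid, dtype=np.int64))
    sheet = Sheet(
        pos=np.ascontiguousarray(np.vstack(pos_blocks)),
        cell_of=np.concatenate(cells),
        params=params,
        growth=growth,
        next_cell_id=n_cells,
    )
    if relax_steps:
        step_dynamics(sheet, dt=dt, n_steps=relax_steps, rng=rng)
    return sheet


def step_dynamics(
    sheet: Sheet,
    dt: float | None = None,
    n_steps: int = 1,
    rng: np.random.Generator | None = None,
    max_disp: float = 0.05,
) -> Sheet:
    """Advance the overdamped dynamics in place; returns the sheet.

    ``dt`` defaults to the stability bound of the potential; ``max_disp``
    (units of d0) caps per-step element displacement.
    """
    p = sheet.params
    if dt is None:
        dt = p.stable_dt
    elif dt > p.relaxation_time:
        raise ValueError(
            f"dt={dt} exceeds the relaxation time {p.relaxation_time:.4g}"
        )
    seed = int((rng or np.random.default_rng()).integers(1 << 31))
    err = mech.run_dynamics(
        sheet.pos, sheet.cell_of, n_steps, dt, p.d0, p.well_depth,
        p.decay_range * p.d0, p.taper_start * p.d0, p.cutoff * p.d0,
        p.intra_scale, p.inter_scale, p.damping, max_disp * p.d0,
        p.noise_amp, seed,
    )
    if err != mech.ERR_OK:
        raise RuntimeError(
            f"dynamics diverged (non-finite position) at t={sheet.time:.3f}, "
            f"N={sheet.n_elements}; reduce dt or check overlaps"
        )
    sheet.time += n_steps * dt
    return sheet


def total_energy(sheet: Sheet) -> float:
    p = sheet.params
    return float(mech.total_energy(
        sheet.pos, sheet.cell_of, p.d0, p.well_depth, p.decay_range * p.d0,
        p.taper_start * p.d0, p.cutoff * p.d0, p.intra_scale, p.inter_scale,
    ))


def _core_mask(sheet: Sheet) -> np.ndarray:
    """Innermost core_fraction of each cell's elements, by centroid distance."""
    mask = np.zeros(sheet.n_elements, dtype=bool)
    frac = sheet.growth.core_fraction
    for cid in sheet.cell_ids:
        idx = np.nonzero(sheet.cell_of == cid)[0]
        d = np.linalg.norm(sheet.pos[idx] - sheet.pos[idx].mean(axis=0), axis=1)
        n_core = max(1, int(math.ceil(frac * len(idx))))
        mask[idx[np.argsort(d, kind="stable")[:n_core]]] = True
    return mask


def attempt_growth(sheet: Sheet, rng: np.random.Generator) -> int:
    """One replication sweep; returns the number of elements added.

    Each core element independently attempts replication with probability
    p_rep: a candidate point a distance ``placement_distance·d0`` away in a
    uniformly random direction is accepted iff its distance to every element
    other than the parent exceeds α·d0.  Rejection is the normal outcome in
    packed tissue.
    """
    g, d0 = sheet.growth, sheet.params.d0
    core = np.nonzero(_core_mask(sheet))[0]
    trying = core[rng.random(len(core)) < g.p_rep]
    if len(trying) == 0:
        return 0
    th = rng.uniform(0, 2 * math.pi, len(trying))
    cand = sheet.pos[trying] + g.placement_distance * d0 * np.column_stack(
        [np.cos(th), np.sin(th)]
    )
    tree = cKDTree(sheet.pos)
    # nearest two existing elements; the parent may or may not be the nearest
    dist, idx = tree.query(cand, k=2)
    clear = np.where(idx[:, 0] == trying, dist[:, 1], dist[:, 0])
    accepted = clear > g.alpha * d0
    if not accepted.any():
        return 0
    new_pos = cand[accepted]
    new_cells = sheet.cell_of[trying[accepted]]
    sheet.pos = np.ascontiguousarray(np.vstack([sheet.pos, new_pos]))
    sheet.cell_of = np.concatenate([sheet.cell_of, new_cells])
    return int(accepted.sum())


def divide_cell(sheet: Sheet, cell_id: int,
                rng: np.random.Generator | None = None,
                random_axis: bool = False) -> tuple[int, int]:
    """Split a doubled cell across its geometric long axis.

    The long axis is the principal eigenvector of the element-position
    covariance; elements are partitioned at the median of their projections
    (so daughter counts differ by at most one) by a cleavage line
    perpendicular to the long axis.  A degenerate (isotropic) covariance or
    ``random_axis=True`` uses a uniformly random axis instead.
    """
    idx = np.nonzero(sheet.cell_of == cell_id)[0]
    if len(idx) < 2:
        raise ValueError(f"cell {cell_id} has fewer than 2 elements")
    X = sheet.pos[idx] - sheet.pos[idx].mean(axis=0)
    if random_axis:
        theta = (rng or np.random.default_rng()).uniform(0, math.pi)
        axis = np.array([math.cos(theta), math.sin(theta)])
    else:
        evals, evecs = np.linalg.eigh(np.cov(X.T))
        if evals[1] - evals[0] <= 1e-12 * max(evals[1], 1.0):
            theta = (rng or np.random.default_rng()).uniform(0, math.pi)
            axis = np.array([math.cos(theta), math.sin(theta)])
        else:
            axis = evecs[:, 1]  # largest eigenvalue
    proj = X @ axis
    order = np.argsort(proj, kind="stable")
    half = len(idx) // 2
    d1, d2 = sheet.next_cell_id, sheet.next_cell_id + 1
    sheet.next_cell_id += 2
    sheet.cell_of[idx[order[:half]]] = d1
    sheet.cell_of[idx[order[half:]]] = d2
    # cleavage line is perpendicular to the long axis
    angle = math.atan2(-axis[0], axis[1]) % math.pi
    sheet.division_log.append(
        DivisionEvent(sheet.time, int(cell_id), d1, d2, angle)
    )
    return d1, d2


def run_growth(
    sheet: Sheet,
    target_cells: int,
    rng: np.random.Generator,
    steps_per_sweep: int = 10,
    dt: float | None = None,
    max_sweeps: int = 500_000,
    random_axis: bool = False,
    progress: bool = False,
) -> Sheet:
    """Interleave relaxation sweeps, replication attempts and divisions.

    Stops once the sheet holds ``target_cells`` cells.  Asserts the adiabatic
    condition up front: the expected number of replications per cell per
    mechanical relaxation time must stay below one.
    """
    if target_cells <= sheet.n_cells:
        raise ValueError("target_cells must exceed the current cell count")
    p, g = sheet.params, sheet.growth
    dt_eff = dt if dt is not None else p.stable_dt
    sweep_time = steps_per_sweep * dt_eff
    reps_per_tau = (2 * g.n0 * g.core_fraction * g.p_rep) * (
        p.relaxation_time / sweep_time
    )
    if reps_per_tau >= 1.0:
        raise ValueError(
            f"adiabatic condition violated: ~{reps_per_tau:.2f} expected "
            "replications per cell per relaxation time (reduce p_rep or "
            "increase steps_per_sweep)"
        )
    for sweep in range(max_sweeps):
        step_dynamics(sheet, dt=dt, n_steps=steps_per_sweep, rng=rng)
        attempt_growth(sheet, rng)
        for cid, cnt in sheet.cell_counts().items():
            if cnt >= 2 * g.n0:
                divide_cell(sheet, cid, rng=rng, random_axis=random_axis)
        if progress and sweep % 200 == 0:
            print(f"sweep {sweep}: {sheet.n_cells} cells, "
                  f"{sheet.n_elements} elements, t={sheet.time:.1f}")
        if sheet.n_cells >= target_cells:
            return sheet
    raise RuntimeError(
        f"target of {target_cells} cells not reached within {max_sweeps} "
        f"sweeps (currently {sheet.n_cells})"
    )


def cell_aspect_ratios(sheet: Sheet) -> dict[int, float]:
    """sqrt(eigenvalue ratio) of each cell's element-position covariance."""
    out = {}
    for cid in sheet.cell_ids:
        X = sheet.elements_of(cid)
        if len(X) < 3:
            continue
        evals = np.linalg.eigvalsh(np.cov((X - X.mean(axis=0)).T))
        out[int(cid)] = float(math.sqrt(max(evals[1], 0) / max(evals[0], 1e-300)))
    return out
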
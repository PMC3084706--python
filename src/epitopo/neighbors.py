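"""Cell-neighbor statistics from element configurations.

Two cells are neighbors when enough of their elements come close: an element
pair (one from each cell) within δ·d0 counts as one contact, and an edge is
drawn when the pair count reaches ``min_contacts`` (1 or 2).  δ is only
meaningful in [1.0, 2.0] — below the equilibrium separation no contact is
defined, beyond the cutoff elements do not interact.  Since the right δ is
not knowable a priori (the same ambiguity arises when counting neighbors in
pixelated micrographs), the selection rule sweeps δ and keeps the histogram
whose interior-cell mean neighbor number is closest to 6, the topological
expectation for a confluent planar tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .distributions import SidednessDistribution
from .scem import DivisionEvent, Sheet

__all__ = [
    "ContactCriterion",
    "contact_graph",
    "interior_cells",
    "cnn_histogram",
    "select_cutoff",
    "reduced_area",
    "axis_isotropy",
    "compare_histograms",
    "mean_cell_diameter",
]

DEFAULT_DELTAS = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)


@dataclass(frozen=True)
class ContactCriterion:
    delta: float = 1.2        # units of d0
    min_contacts: int = 1

    def __post_init__(self) -> None:
        if self.delta < 1.0:
            raise ValueError(
                f"delta={self.delta}: below the equilibrium distance no "
                "contact is defined (need delta >= 1.0)"
            )
        if self.min_contacts < 1:
            raise ValueError("min_contacts must be at least 1")


def contact_graph(sheet: Sheet, criterion: ContactCriterion) -> nx.Graph:
    """Cell-adjacency graph under an element-distance criterion.

    Nodes are all cell ids; edge (A, B) carries ``n_pairs``, the number of
    cross-cell element pairs within δ·d0, and exists iff that count reaches
    ``min_contacts``.  Uses a k-d tree, so cost is near-linear in elements.
    """
    g = nx.Graph()
    g.add_nodes_from(int(c) for c in sheet.cell_ids)
    tree = cKDTree(sheet.pos)
    pairs = tree.query_pairs(criterion.delta * sheet.params.d0,
                             output_type="ndarray")
    if len(pairs) == 0:
        return g
    ca = sheet.cell_of[pairs[:, 0]]
    cb = sheet.cell_of[pairs[:, 1]]
    cross = ca != cb
    lo = np.minimum(ca[cross], cb[cross])
    hi = np.maximum(ca[cross], cb[cross])
    if len(lo) == 0:
        return g
    edges, counts = np.unique(np.column_stack([lo, hi]), axis=0,
                              return_counts=True)
    for (a, b), c in zip(edges, counts):
        if c >= criterion.min_contacts:
            g.add_edge(int(a), int(b), n_pairs=int(c))
    return g


def mean_cell_diameter(sheet: Sheet) -> float:
    """Equivalent-area mean cell diameter from the sheet's convex hull."""
    hull = MultiPoint(sheet.pos).convex_hull
    return math.sqrt(4.0 * hull.area / (math.pi * sheet.n_cells))


def interior_cells(sheet: Sheet, margin: float | None = None) -> set[int]:
    """Cells whose every element lies at least ``margin`` inside the hull.

    ``margin`` is in simulation length units (d0 = 1); the default is one
    mean cell diameter, which strips the free boundary where neighbor counts
    are unreliable.
    """
    if margin is None:
        margin = mean_cell_diameter(sheet)
    hull = MultiPoint(sheet.pos).convex_hull
    boundary = hull.exterior
    depth = shapely.distance(shapely.points(sheet.pos), boundary)
    interior = set()
    for cid in sheet.cell_ids:
        if depth[sheet.cell_of == cid].min() >= margin:
            interior.add(int(cid))
    if not interior:
        raise ValueError(
            f"no interior cells at margin={margin:.3g}; sheet too small "
            "or margin too large"
        )
    return interior


def cnn_histogram(graph: nx.Graph, include: set[int]) -> SidednessDistribution:
    """Fraction of included cells by contact-graph degree."""
    if not include:
        raise ValueError("empty include set")
    missing = include - set(graph.nodes)
    if missing:
        raise ValueError(f"cells not in graph: {sorted(missing)[:5]}")
    degrees = np.array([graph.degree(c) for c in include])
    counts = np.bincount(degrees, minlength=3)
    return SidednessDistribution.from_counts(counts)


def select_cutoff(
    sheet: Sheet,
    deltas=DEFAULT_DELTAS,
    min_contacts: int = 1,
    margin: float | None = None,
):
    """Sweep δ and keep the cutoff whose interior mean CNN is closest to 6.

    Returns ``(delta, histogram, sweep)`` where ``sweep`` is a DataFrame of
    (delta, mean_degree).  Ties break toward smaller δ.
    """
    import pandas as pd

    deltas = sorted(deltas)
    if deltas[0] < 1.0 or deltas[-1] > 2.0:
        raise ValueError("deltas must lie within [1.0, 2.0]")
    include = interior_cells(sheet, margin=margin)
    rows, hists = [], []
    for d in deltas:
        g = contact_graph(sheet, ContactCriterion(d, min_contacts))
        h = cnn_histogram(g, include)
        rows.append({"delta": d, "mean_degree": h.mean()})
        hists.append(h)
    sweep = pd.DataFrame(rows)
    best = int(np.argmin(np.abs(sweep["mean_degree"].to_numpy() - 6.0)))
    return deltas[best], hists[best], sweep


def reduced_area(sheet: Sheet, cell_id: int) -> float:
    """Isoperimetric shape factor 4πA/P² of the cell outline.

    The outline is the convex hull of the cell's elements dilated by d0/2
    (elements are discs of diameter d0).  1 for a circle, π/4 for a square;
    elongated cells score lower.
    """
    pts = sheet.elements_of(cell_id)
    if len(pts) < 3:
        raise ValueError(f"cell {cell_id} has fewer than 3 elements")
    outline = MultiPoint(pts).convex_hull.buffer(sheet.params.d0 / 2,
                                                 quad_segs=64)
    if outline.is_empty or outline.length == 0:
        raise ValueError(f"degenerate outline for cell {cell_id}")
    return 4.0 * math.pi * outline.area / outline.length**2


def shape_factor(area: float, perimeter: float) -> float:
    return 4.0 * math.pi * area / perimeter**2


def axis_isotropy(events) -> tuple[float, float]:
    """Rayleigh uniformity test on division-axis orientations.

    Accepts a sequence of DivisionEvent or of angles (radians).  Axes are
    orientations mod π, so the test runs on doubled angles.  Returns
    (mean resultant length Rbar, p-value); small p rejects uniformity.
    """
    angles = np.asarray([
        e.axis_angle if isinstance(e, DivisionEvent) else float(e)
        for e in events
    ])
    n = len(angles)
    if n < 30:
        raise ValueError(f"need at least 30 division events, got {n}")
    z = np.exp(2j * angles)
    rbar = float(abs(z.mean()))
    # Rayleigh Z with the standard small-sample correction
    Z = n * rbar * rbar
    p = math.exp(-Z) * (
        1 + (2 * Z - Z * Z) / (4 * n)
        - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n * n)
    )
    return rbar, float(min(max(p, 0.0), 1.0))


def compare_histograms(
    h1: SidednessDistribution, h2: SidednessDistribution
) -> dict[str, float]:
    """L1 distance (in [0, 2]) and symmetric chi-square between histograms."""
    n = max(h1.s_max, h2.s_max)
    a, b = h1.padded(n), h2.padded(n)
    nz = (a + b) > 0
    chi2 = float(((a[nz] - b[nz]) ** 2 / (a[nz] + b[nz])).sum())
    return {"l1": float(np.abs(a - b).sum()), "chi2": chi2}
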
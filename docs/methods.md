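# Methods

## Division kernels

A dividing m-sided cell has m vertices; a straight cleavage line gives each
daughter two new vertices, so a daughter inheriting k mother vertices has
j = k + 2 sides and its sister has m + 4 − j.  The kernel P(j | m) encodes
how the cleavage orientation distributes vertices:

- **gpnp weights**: (q − 2) vertices are pre-placed on each side (q = minimum
  daughter sidedness) and the remaining m − 2(q − 2) are assigned to either
  side independently with probability 1/2 — a shifted symmetric binomial.
- **strict weights**: all m vertices are assigned i.i.d. and outcomes in
  which a daughter falls below q sides are discarded, renormalizing the
  rest.  This is the distribution implied by a cleavage axis chosen purely
  at random, with no mechanism privileging any vertex.

q = 4 forbids sub-quadrilateral daughters; q = 3 allows transient triangles;
q = 2 (strict weights, no per-side minimum, so nothing is discarded and
P(k) = C(m, k)/2^m) allows transient 2-sided cells.  Rows are computed with
exact integer combinatorics and normalized once by construction; tests
compare every row for m ≤ 12 against exhaustive enumeration of all vertex
placements and check the exact identities Σ_j P(j|m) = 1,
P(j|m) = P(m+4−j|m), and E[j] = (m+4)/2 to 1e-12 (one float division is the
only rounding).  The kernel is tabulated up to m_max (default 64 for the
chain, 192 for the process, where rare many-sided cells arise).

## Synchronous chain

State: fractions p_s, s up to a truncation window s_max (default 64).  One
generation is q = K·p (daughter mixture; populations double but fractions
are invariant to the doubling) followed by a shift s → s + 1.  The shift is
the mean-field account of side gain: each division donates one side to each
of two neighbors, and with N divisions among N cells every cell gains one
side per generation on average.

The post-shift (end-of-generation) state is what `steady_state` reports;
`division_step` exposes the intermediate post-division state, which is where
transient 3-sided daughters are visible — after the shift their fraction is
identically zero, which is how the "decreases to zero" behavior appears in
end-of-generation bookkeeping.

Numerics: default start δ(s=6); convergence when the L1 change per
generation falls below 1e-12 (about 20 generations — the mean error halves
each generation and the shape converges at a similar rate).  Mass that
attempts to pass s_max raises an error rather than being clipped; a spill
below 1e-13 per generation is treated as zero so that the window does not
need to grow with the iteration count.  The fixed point is verified
independent of the start and of s_max ≥ 40 to 1e-10.

## Asynchronous process

State: integer counts N_s.  Each divisible cell carries propensity λ
(classes with no legal split — possible only transiently below the kernel's
minimum divisible sidedness — carry zero).  An event, executed as one atomic
block: exponential waiting time at total rate λ·N_div; mother chosen
uniformly per cell among divisible classes; daughters j, m+4−j sampled from
the kernel row; then two side recipients chosen uniformly per cell from the
post-division population, as two sequential draws from the running counts —
so the second draw can hit the first recipient again (now one side richer).
A `distinct_recipients` flag excludes it instead; the difference is O(1/N).
λ is a pure time scale: histograms depend only on event counts, so λ = 1.

The inner loop is numba-compiled and tracks only the ~60 occupied classes;
10⁶ cells take about one second.  A pure-python `gillespie_step` implements
the identical event block; both paths are tested against an exact recursive
enumeration of all event trees for 3 → 6-cell populations (agreement within
5σ multinomial bands at 10⁴–2·10⁴ realizations) and both conserve the
invariant ΔN = +1, Δ(total sides) = +6 per event exactly.  The default
quasi-steady-state protocol grows 10³ → 10⁶ cells; the histogram is read
from the relative fractions of the single final state (the population is
self-averaging at that size — bin fluctuations shrink as N^(−1/2), tested
across seeds).

## Subcellular-element tissue

Units: element diameter d0 = 1 (length), drag γ = 1 (time scale γ·ρ²/2ε),
well depth ε = 1 (energy).  Pair potential: Morse,
U(r) = ε[(1 − e^{−(r−d0)/ρ})² − 1] with decay ρ = 0.25·d0, multiplied by a
cubic smoothstep that takes potential and force smoothly to zero between
1.6·d0 and the hard cutoff 2.0·d0.  Force is zero at d0, repulsive below,
attractive above.  Same-cell pairs use scale 1.0, cross-cell pairs 0.5 —
cohesion within a cell exceeds adhesion between cells, qualitatively
matching the ~4:1 modulus-to-adhesion ratio measured for embryonic cells.
The mapping to physical units (kPa-scale moduli, ~1 s relaxation) is a
documented correspondence only; no rheology is validated here.

Integration: overdamped Euler, dx = F/γ·dt, default dt = half the relaxation
time γρ²/2ε (dt larger than the relaxation time is rejected).  A per-step
displacement cap of 0.05·d0 keeps freshly inserted elements (which start
deeply overlapped) from destabilizing the integrator; in relaxed
configurations the cap never binds and the update is plain gradient descent,
verified by a monotone-energy test.  Thermal noise is available
(`noise_amp`) but off by default — growth stochasticity already provides
disorder.  Neighbor search uses a cell-linked grid at the cutoff radius, so
a force evaluation is linear in element count.

Growth: every sweep (10 dynamics steps), each *core* element — the innermost
`core_fraction` = 0.5 of a cell's elements by centroid distance — attempts
replication with probability p_rep = 0.01.  A candidate point is proposed at
distance d0/2 from the parent in a uniformly random direction and accepted
iff its distance to every element *other than the parent* exceeds α·d0.
(The parent must be excluded: it sits at d0/2 < α·d0 by construction, and
the model's limit case — a lone element — must accept with probability 1.)
α ∈ (0.5, 1.0); defaults follow the biologically constrained range around
0.54–0.56, with 0.55 used in the standard run.  Raising α makes placement
more space-sensitive and strictly shrinks the acceptance set, which is how
the proliferation rate is tuned.  The adiabatic condition — expected
replications per cell per relaxation time below one — is asserted at run
start; under it, element density stays uniform across the sheet (tested:
coefficient of variation < 20% over interior cells).

Division: when a cell reaches 2·n0 elements, its long axis is the principal
eigenvector of the element-position covariance and the cleavage line runs
perpendicular to it through the cell.  Elements are partitioned at the
*median* projection rather than the centroid: this guarantees daughter
counts differ by at most one ("splits evenly") and coincides with the
centroid split for symmetric clouds.  Isotropic-to-machine-precision
covariance falls back to a random axis.  The cleavage-line orientation
(mod π) is logged per event; over a grown run these orientations are
uniform (Rayleigh test on doubled angles, non-rejection at 1%).  Forcing
the axis random in space instead produces the elongated, "splintered"
morphologies the long-axis rule exists to avoid (tested by comparing median
aspect ratios).

Boundary: free — the sheet grows outward from a hexagonally seeded array
(37 cells of n0 elements, sunflower disc packings, relaxed before growth).

**Problem sizes.**  The standard profile here is desk-scale: n0 = 32
elements per newborn cell, 37 seed cells grown to 150 (≈6,500 elements,
~110 division events, about two minutes).  The full-scale profile
(n0 = 128, 1000–1500 cells) is the same code path and is exposed through
the CLI/config, but all shipped tests and the acceptance script use the
desk profile; the interior-cell statistics of interest (mean CNN within 0.1
of 6 at the selected cutoff) are already stable at that size.

## Neighbor counting

Contact: an element pair from different cells within δ·d0, δ ∈ [1.0, 2.0]
(below the equilibrium separation no contact is defined; beyond the cutoff
elements do not interact).  An edge requires ≥ `min_contacts` pairs (1 or
2 — both conventions exist in the experimental literature).  Contact graphs
are nested in δ and anti-nested in min_contacts, and the k-d-tree
implementation is tested against an all-pairs oracle.

Since δ is not knowable a priori — the same ambiguity afflicts neighbor
counting in pixelated micrographs — `select_cutoff` sweeps a δ grid
(default 1.0 to 2.0 in steps of 0.2) and keeps the histogram whose
interior-cell mean degree is closest to 6, the topological expectation for
a confluent planar tissue; ties break toward smaller δ.  Interior cells are
those whose every element lies at least one mean cell diameter
(equivalent-area, from the sheet hull) inside the convex hull of all
elements; the margin is a parameter, and for few-cell fixtures an explicit
smaller margin is appropriate since a one-diameter band can cover the whole
sheet.  Note the interior mean degree can sit slightly above 6: interior
cells keep their edges to excluded near-boundary cells, so the global
planar-graph bound (mean degree < 6) does not apply to the subset.

Shape statistic: reduced area 4πA/P² of the cell outline, taken as the
convex hull of the cell's elements dilated by d0/2 (elements are discs).
It is 1 for a circle, π/4 for a square; a single grown tissue spans an
interquartile range above 0.05, which is why it cannot serve as a sharp
per-tissue order parameter.  The convex-hull outline slightly overestimates
the reduced area of concave cells; grown cells here are close to convex, so
the bias is small, but the outline rule is isolated behind `reduced_area`
for replacement.

## Synthetic fixtures

`hex_sheet_fixture` provides sheets with *exactly* known topology: one
global triangular element lattice (spacing d0) partitioned into congruent
centered-hexagonal patches, one per cell, via an Eisenstein-integer
superlattice whose index equals the patch size.  Every cross-boundary
nearest element pair sits at exactly d0, so at zero jitter each interior
cell has exactly six neighbors for any δ ∈ [1.0, √3).  This makes the
neighbor-counting layer testable without simulation.  The price: elements
per cell is rounded up to a centered hexagonal number (1, 7, 19, 37, …).
The fixture emulates topology only — it has no mechanics, no cell-shape
variability, and no boundary disorder, so passing fixture tests validates
the counting layer, not the tissue model.

## Known limitations

- Strictly two-dimensional; mitotic rounding and columnar–spherical shape
  transitions of real epithelia are not modeled.
- No cell death or ingression in the spatial tier; the process model's
  broad histogram is the only account of ingression-dominated tissue here.
- Growth rate has no cell-size or mechanics feedback beyond the α-gated
  clearance rule.
- Mechanical parameters are in simulation units; the physical calibration
  is a correspondence, not a fit.
- Experimental CNN histograms exist in the source literature only as
  figures and are not reproduced numerically; comparisons against them go
  through user-supplied histogram CSVs.
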
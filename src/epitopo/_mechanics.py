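"""Numba kernels for the subcellular-element mechanics.

Pair interaction: a Morse potential with equilibrium at the element diameter
d0, multiplied by a smoothstep switching function that takes the potential
(and force) smoothly to zero at the cutoff.  Same-cell and different-cell
pairs use the same shape scaled by ``intra`` / ``inter``.  Dynamics are
overdamped: dx = F/γ·dt (+ optional thermal noise), with a per-step
displacement cap that keeps freshly inserted, strongly overlapping elements
from destabilizing the integrator.
"""

import numpy as np
from numba import njit

ERR_OK = 0
ERR_NONFINITE = 1


@njit(cache=True, inline="always")
def _pair(dist, d0, eps, rho, r_taper, rc):
    """(energy, radial force) of the tapered Morse pair at separation dist."""
    e = np.exp(-(dist - d0) / rho)
    u = eps * ((1.0 - e) ** 2 - 1.0)
    du = 2.0 * eps * (1.0 - e) * e / rho
    if dist <= r_taper:
        return u, -du
    t = (dist - r_taper) / (rc - r_taper)
    s = 1.0 - 3.0 * t * t + 2.0 * t * t * t
    ds = (-6.0 * t + 6.0 * t * t) / (rc - r_taper)
    return u * s, -(du * s + u * ds)


@njit(cache=True)
def _build_grid(pos, rc):
    n = pos.shape[0]
    xmin = pos[:, 0].min()
    ymin = pos[:, 1].min()
    nx = int((pos[:, 0].max() - xmin) / rc) + 1
    ny = int((pos[:, 1].max() - ymin) / rc) + 1
    head = -np.ones(nx * ny, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - xmin) / rc)
        cy = int((pos[i, 1] - ymin) / rc)
        b = cy * nx + cx
        nxt[i] = head[b]
        head[b] = i
    return head, nxt, xmin, ymin, nx, ny


@njit(cache=True)
def compute_forces(pos, cell_of, d0, eps, rho, r_taper, rc, intra, inter):
    n = pos.shape[0]
    F = np.zeros((n, 2))
    head, nxt, xmin, ymin, nx, ny = _build_grid(pos, rc)
    for i in range(n):
        cx = int((pos[i, 0] - xmin) / rc)
        cy = int((pos[i, 1] - ymin) / rc)
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                gx = cx + ox
                gy = cy + oy
                if gx < 0 or gx >= nx or gy < 0 or gy >= ny:
                    continue
                j = head[gy * nx + gx]
                while j >= 0:
                    if j > i:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        d2 = dx * dx + dy * dy
                        if d2 < rc * rc and d2 > 1e-20:
                            dist = np.sqrt(d2)
                            _, fr = _pair(dist, d0, eps, rho, r_taper, rc)
                            scale = intra if cell_of[i] == cell_of[j] else inter
                            fx = scale * fr * dx / dist
                            fy = scale * fr * dy / dist
                            F[i, 0] += fx
                            F[i, 1] += fy
                            F[j, 0] -= fx
                            F[j, 1] -= fy
                    j = nxt[j]
    return F


@njit(cache=True)
def total_energy(pos, cell_of, d0, eps, rho, r_taper, rc, intra, inter):
    n = pos.shape[0]
    E = 0.0
    head, nxt, xmin, ymin, nx, ny = _build_grid(pos, rc)
    for i in range(n):
        cx = int((pos[i, 0] - xmin) / rc)
        cy = int((pos[i, 1] - ymin) / rc)
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                gx = cx + ox
                gy = cy + oy
                if gx < 0 or gx >= nx or gy < 0 or gy >= ny:
                    continue
                j = head[gy * nx + gx]
                while j >= 0:
                    if j > i:
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        d2 = dx * dx + dy * dy
                        if d2 < rc * rc and d2 > 1e-20:
                            dist = np.sqrt(d2)
                            u, _ = _pair(dist, d0, eps, rho, r_taper, rc)
                            scale = intra if cell_of[i] == cell_of[j] else inter
                            E += scale * u
                    j = nxt[j]
    return E


@njit(cache=True)
def run_dynamics(pos, cell_of, n_steps, dt, d0, eps, rho, r_taper, rc,
                 intra, inter, damping, max_disp, noise_amp, seed):
    """In-place overdamped integration; returns an error code."""
    np.random.seed(seed)
    n = pos.shape[0]
    for _ in range(n_steps):
        F = compute_forces(pos, cell_of, d0, eps, rho, r_taper, rc, intra, inter)
        for i in range(n):
            ux = F[i, 0] * dt / damping
            uy = F[i, 1] * dt / damping
            if noise_amp > 0.0:
                amp = noise_amp * np.sqrt(dt)
                ux += amp * np.random.normal()
                uy += amp * np.random.normal()
            mag = np.sqrt(ux * ux + uy * uy)
            if mag > max_disp:
                ux *= max_disp / mag
                uy *= max_disp / mag
            pos[i, 0] += ux
            pos[i, 1] += uy
            if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])):
                return ERR_NONFINITE
    return ERR_OK
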
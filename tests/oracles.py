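"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately share no code with the implementation: the lattice oracle
enumerates every ligand placement explicitly, the Hill oracle is a coarse
grid-search minimizer, and the superposition oracle searches rotations on a
zooming Euler-angle grid.
"""

from __future__ import annotations

import numpy as np


def enumerate_lattice(L: int, m: int, omega: float) -> dict[int, float]:
    """Sum of omega^(contacts) over all placements, resolved by ligand count.

    Explicit recursion over ligand start positions; a contact is two ligands
    whose footprints abut exactly.
    """
    weights: dict[int, float] = {0: 1.0}

    def place(next_start: int, prev_end: int, k: int, w: float) -> None:
        for start in range(next_start, L - m + 2):  # 1-based starts
            contact = omega if (prev_end >= 0 and start == prev_end + 1) else 1.0
            wk = w * contact
            weights[k + 1] = weights.get(k + 1, 0.0) + wk
            place(start + m, start + m - 1, k + 1, wk)

    place(1, -1, 0, 1.0)
    return weights


def enumerate_occupancy(L: int, m: int, omega: float, k_assoc: float, conc: float) -> np.ndarray:
    """Occupancy probabilities from the enumeration oracle."""
    w = enumerate_lattice(L, m, omega)
    k_max = max(w)
    z = np.array([w.get(k, 0.0) * (k_assoc * conc) ** k for k in range(k_max + 1)])
    return z / z.sum()


def grid_search_hill(conc: np.ndarray, frac: np.ndarray,
                     kd_grid=None, h_grid=None, bmax_grid=None) -> tuple[float, float, float, float]:
    """Coarse grid-search least squares for the Hill isotherm.

    Returns (kd, h, bmax, sse) at the grid minimum.
    """
    kd_grid = np.geomspace(1.0, 1e4, 160) if kd_grid is None else kd_grid
    h_grid = np.linspace(0.3, 6.0, 58) if h_grid is None else h_grid
    bmax_grid = np.linspace(0.5, 1.2, 36) if bmax_grid is None else bmax_grid
    pos = conc > 0
    best = (np.nan, np.nan, np.nan, np.inf)
    for h in h_grid:
        ch = np.zeros_like(conc)
        for kd in kd_grid:
            r = (conc[pos] / kd) ** h
            ch[pos] = r / (1.0 + r)
            # optimal bmax restricted to its grid
            for bmax in bmax_grid:
                sse = float(np.sum((bmax * ch - frac) ** 2))
                if sse < best[3]:
                    best = (float(kd), float(h), float(bmax), sse)
    return best


def _euler_matrix(a: float, b: float, c: float) -> np.ndarray:
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def rotation_grid_rmsd(mobile: np.ndarray, target: np.ndarray,
                       levels: int = 7, coarse_step: float = np.radians(20)) -> float:
    """Minimum superposition RMSD by zooming Euler-angle grid search."""
    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)

    def rmsd_at(a, b, c):
        R = _euler_matrix(a, b, c)
        return float(np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1))))

    best_angles, best = (0.0, 0.0, 0.0), rmsd_at(0, 0, 0)
    for a in np.arange(-np.pi, np.pi, coarse_step):
        for b in np.arange(0, np.pi + 1e-9, coarse_step):
            for c in np.arange(-np.pi, np.pi, coarse_step):
                r = rmsd_at(a, b, c)
                if r < best:
                    best, best_angles = r, (a, b, c)
    step = coarse_step
    for _ in range(levels):
        step *= 0.25
        a0, b0, c0 = best_angles
        for a in a0 + step * np.arange(-3, 4):
            for b in b0 + step * np.arange(-3, 4):
                for c in c0 + step * np.arange(-3, 4):
                    r = rmsd_at(a, b, c)
                    if r < best:
                        best, best_angles = r, (a, b, c)
    return best
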
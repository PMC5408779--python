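"""Low-level cellular-Potts (GGH) lattice kernel.

The lattice is a (rows, cols) integer array of cell ids: 0 = MEDIUM,
1 = SUPPORT (immobile basement layer), ids >= 2 = epithelial cells.
Columns wrap periodically (the crypt base unrolled around its
circumference); rows do not (row 0 is the bottom of the crypt).

One Monte-Carlo step (MCS) performs rows*cols random pixel-copy attempts.
A copy attempt proposes overwriting a random site with the id of one of its
8 neighbors and is accepted with the Boltzmann rule min(1, exp(-dE/T)),
where E sums heterotypic contact energies J over 4-neighbor pairs plus the
quadratic volume constraint lambda_vol (v - v_target)^2 of every cell.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MEDIUM = 0
SUPPORT = 1
FIRST_CELL_ID = 2

# cell-type codes (index into the adhesion table)
T_MEDIUM = 0
T_SUPPORT = 1
T_STEM = 2
T_PANETH = 3
N_TYPES = 4


@njit(cache=False)
def potts_mcs(
    lattice: np.ndarray,
    type_of_id: np.ndarray,
    volumes: np.ndarray,
    target_vol: np.ndarray,
    J: np.ndarray,
    lambda_vol: float,
    temperature: float,
    seed: int,
) -> float:
    """Run one MCS in place; returns the accumulated accepted energy change."""
    np.random.seed(seed)
    H, W = lattice.shape
    dE_total = 0.0
    for _attempt in range(H * W):
        x = np.random.randint(0, H)
        y = np.random.randint(0, W)
        t_id = lattice[x, y]
        if t_id == SUPPORT:
            continue
        dx = np.random.randint(-1, 2)
        dy = np.random.randint(-1, 2)
        if dx == 0 and dy == 0:
            continue
        nx = x + dx
        if nx < 0 or nx >= H:
            continue
        ny = (y + dy) % W
        s_id = lattice[nx, ny]
        if s_id == SUPPORT or s_id == t_id:
            continue
        if t_id >= FIRST_CELL_ID and volumes[t_id] <= 1:
            continue  # never annihilate a cell by fluctuation
        t_type = type_of_id[t_id]
        s_type = type_of_id[s_id]
        # adhesion change over the 4-neighborhood of the flipped site
        dE = 0.0
        for k in range(4):
            if k == 0:
                ux, uy = x - 1, y
            elif k == 1:
                ux, uy = x + 1, y
            elif k == 2:
                ux, uy = x, (y - 1) % W
            else:
                ux, uy = x, (y + 1) % W
            if ux < 0 or ux >= H:
                continue
            u_id = lattice[ux, uy]
            u_type = type_of_id[u_id]
            if u_id != s_id:
                dE += J[s_type, u_type]
            if u_id != t_id:
                dE -= J[t_type, u_type]
        # volume-constraint change
        if t_id >= FIRST_CELL_ID:
            v = volumes[t_id]
            tv = target_vol[t_id]
            dE += lambda_vol * ((v - 1 - tv) ** 2 - (v - tv) ** 2)
        if s_id >= FIRST_CELL_ID:
            v = volumes[s_id]
            tv = target_vol[s_id]
            dE += lambda_vol * ((v + 1 - tv) ** 2 - (v - tv) ** 2)
        if dE <= 0.0 or (temperature > 0.0 and np.random.random() < np.exp(-dE / temperature)):
            lattice[x, y] = s_id
            if t_id >= FIRST_CELL_ID:
                volumes[t_id] -= 1
            if s_id >= FIRST_CELL_ID:
                volumes[s_id] += 1
            dE_total += dE
    return dE_total


def total_energy(
    lattice: np.ndarray,
    type_of_id: np.ndarray,
    volumes: np.ndarray,
    target_vol: np.ndarray,
    J: np.ndarray,
    lambda_vol: float,
) -> float:
    """Recompute the full GGH energy from scratch (audit of the kernel)."""
    H, W = lattice.shape
    E = 0.0
    right = np.roll(lattice, -1, axis=1)
    pairs = [(lattice, right)]
    pairs.append((lattice[:-1, :], lattice[1:, :]))
    for a, b in pairs:
        mask = a != b
        E += J[type_of_id[a[mask]], type_of_id[b[mask]]].sum()
    for cid in range(FIRST_CELL_ID, len(volumes)):
        if volumes[cid] > 0:
            E += lambda_vol * (volumes[cid] - target_vol[cid]) ** 2
    return float(E)


def contact_counts(lattice: np.ndarray, n_ids: int) -> np.ndarray:
    """Shared boundary lengths between all id pairs (4-neighborhood).

    Returns a symmetric (n_ids, n_ids) matrix of boundary-segment counts;
    rows/columns 0 and 1 are MEDIUM and SUPPORT.
    """
    C = np.zeros((n_ids, n_ids), dtype=np.int64)
    for a, b in (
        (lattice[:, :-1].ravel(), lattice[:, 1:].ravel()),
        (lattice[:, -1], lattice[:, 0]),  # periodic column wrap
        (lattice[:-1, :].ravel(), lattice[1:, :].ravel()),
    ):
        mask = a != b
        np.add.at(C, (a[mask], b[mask]), 1)
    return C + C.T
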
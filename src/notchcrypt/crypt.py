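"""Stochastic cellular-Potts model of the crypt base stem-cell niche.

A 2-D GGH lattice represents the unrolled bottom of an intestinal crypt: an
immobile SUPPORT stripe (basement membrane) along the bottom row, covered
by a monolayer of epithelial cells, with MEDIUM above.  Every epithelial
cell in the niche zone carries a Notch signaling state (NOTCH, DLL, NICD)
advanced each Monte-Carlo step by the circuit ODEs, with neighbor means
weighted by shared contact length.  NICD above a threshold marks a cell as
a Notch-high stem (CBC-like) cell, which grows and divides; Notch-low
(Paneth-like) cells neither grow nor divide.  Cells that detach from the
support die by anoikis; cells pushed above the niche zone are removed
(upward migration out of the crypt base).  The ``turnover_multiplier``
scales the stem-cell growth rate and thereby the rates of division,
migration, and anoikis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._potts import (
    FIRST_CELL_ID,
    MEDIUM,
    N_TYPES,
    SUPPORT,
    T_MEDIUM,
    T_PANETH,
    T_STEM,
    T_SUPPORT,
    contact_counts,
    potts_mcs,
    total_energy,
)
from .circuits import CircuitParams, rhs_model3
from .lattice import NeighborGraph, checkerboard_score
from .patterning import homogeneous_fixed_point
from .stats import bimodality

__all__ = [
    "CryptConfig",
    "CryptWorld",
    "CryptRun",
    "default_adhesion_table",
    "auto_nicd_threshold",
    "init_crypt",
    "potts_step",
    "signaling_step",
    "fate_update",
    "divide_cell",
    "anoikis_and_exit",
    "run_crypt",
    "pf_strength_sweep",
    "niche_contact_graph",
]


def default_adhesion_table() -> np.ndarray:
    """Symmetric contact-energy table indexed by (type, type).

    Cell--support contact is the cheapest (cells adhere to the basement
    membrane), cell--cell contact is moderate, and cell--medium contact is
    expensive (epithelial cells minimize free apical surface), which keeps
    the monolayer cohesive without gluing cells in place.
    """
    J = np.zeros((N_TYPES, N_TYPES))
    cells = (T_STEM, T_PANETH)
    for a in cells:
        for b in cells:
            J[a, b] = 6.0
        J[a, T_MEDIUM] = J[T_MEDIUM, a] = 16.0
        J[a, T_SUPPORT] = J[T_SUPPORT, a] = 3.0
    J[T_MEDIUM, T_SUPPORT] = J[T_SUPPORT, T_MEDIUM] = 14.0
    return J


@dataclass
class CryptConfig:
    """Geometry, energies, and coupling constants of the crypt model."""

    width: int = 300              # lattice columns (periodic; crypt circumference)
    height: int = 40              # lattice rows (row 0 = crypt bottom)
    support_rows: int = 4         # thickness of the basement-membrane stripe
    cell_size: int = 5            # initial side length of seeded cells (pixels)
    epithelial_rows: int = 1      # rows of seeded cells (monolayer on the support)
    niche_top: int = 11           # cells with centroid above this row leave the niche
    lambda_volume: float = 2.0    # strength of the volume constraint
    potts_temperature: float = 6.0
    target_volume: int = 25       # initial/reference cell volume (pixels)
    growth_rate: float = 0.09     # target-volume increment per MCS for stem cells
    division_volume: int = 45     # volume threshold triggering division
    turnover_multiplier: float = 1.0
    nicd_threshold: Optional[float] = None  # None: derived from the pair analysis
    mcs_per_ode_step: int = 1
    ode_dt: float = 0.01          # dimensionless signaling time per MCS
    init_noise: float = 0.01
    n_mcs: int = 1500
    sample_every: int = 20
    seed: int = 0
    allow_reversion: bool = True  # Notch-low cells keep signaling and may revert
    adhesion_J: Optional[list] = None  # 4x4 nested list; None -> default table

    def __post_init__(self) -> None:
        if self.turnover_multiplier <= 0:
            raise ValueError("turnover_multiplier must be > 0")
        if self.growth_rate < 0 or self.division_volume <= 0 or self.target_volume <= 0:
            raise ValueError("growth and volume parameters must be positive")
        if self.support_rows + self.epithelial_rows * self.cell_size >= self.height:
            raise ValueError("lattice too short for the requested cell layers")
        if self.width % self.cell_size != 0:
            raise ValueError("width must be a multiple of cell_size")
        J = self.J_table()
        if not np.allclose(J, J.T):
            raise ValueError("adhesion table must be symmetric")

    def J_table(self) -> np.ndarray:
        if self.adhesion_J is None:
            return default_adhesion_table()
        return np.asarray(self.adhesion_J, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["adhesion_J"] is not None:
            d["adhesion_J"] = np.asarray(d["adhesion_J"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CryptConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CryptConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class CryptWorld:
    """Mutable state of a crypt simulation."""

    config: CryptConfig
    params: CircuitParams
    lattice: np.ndarray
    cell_type: np.ndarray          # per-id type code
    volumes: np.ndarray            # per-id pixel counts
    target_vol: np.ndarray         # per-id target volumes
    signaling: np.ndarray          # per-id (N, D, R)
    alive: np.ndarray              # per-id liveness
    nicd_threshold: float
    energy: float
    mcs: int = 0
    next_id: int = FIRST_CELL_ID
    events: list = field(default_factory=list)
    _potts_seeds: np.ndarray = field(default=None, repr=False)
    _division_rng: np.random.Generator = field(default=None, repr=False)

    def live_cells(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def cell_count(self) -> int:
        return int(self.alive.sum())

    def centroid_rows(self) -> dict[int, float]:
        flat = self.lattice.ravel()
        row_idx = np.repeat(np.arange(self.lattice.shape[0]), self.lattice.shape[1])
        sums = np.bincount(flat, weights=row_idx, minlength=self.next_id)
        counts = np.bincount(flat, minlength=self.next_id)
        return {
            int(cid): float(sums[cid] / counts[cid])
            for cid in self.live_cells()
            if counts[cid] > 0
        }

    def niche_cells(self) -> np.ndarray:
        """Live cells whose centroid lies inside the signaling (niche) zone."""
        rows = self.centroid_rows()
        return np.array(
            [cid for cid, r in rows.items() if r < self.config.niche_top], dtype=int
        )

    def log(self, kind: str, cell_id: int, **extra) -> None:
        self.events.append({"mcs": self.mcs, "event": kind, "cell_id": int(cell_id), **extra})

    def _ensure_capacity(self, n: int) -> None:
        cap = len(self.volumes)
        if n < cap:
            return
        new = max(n + 1, 2 * cap)
        for name in ("cell_type", "volumes", "target_vol", "alive"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            grown[:cap] = arr
            setattr(self, name, grown)
        sig = np.zeros((new, 3))
        sig[:cap] = self.signaling
        self.signaling = sig

    def recompute_energy(self) -> float:
        return total_energy(
            self.lattice, self.cell_type, self.volumes, self.target_vol,
            self.config.J_table(), self.config.lambda_volume,
        )


import functools


@functools.lru_cache(maxsize=64)
def auto_nicd_threshold(params: CircuitParams) -> float:
    """Stem/Paneth NICD boundary derived from the pair-cell analysis.

    The midpoint between the high and low NICD levels of the pair's
    patterned (asymmetric stable) state; falls back to the homogeneous
    steady-state NICD when the pair is not bistable.
    """
    from .dynamics import pair_fixed_points
    from .lattice import NeighborGraph

    pts = [ss for ss in pair_fixed_points(params) if ss.is_stable]
    asym = [ss for ss in pts if not np.allclose(ss.state[0], ss.state[1], rtol=1e-4)]
    if asym:
        best = max(asym, key=lambda ss: float(np.ptp(ss.state[:, 2])))
        r_lo, r_hi = sorted(best.state[:, 2])
        return float(0.5 * (r_lo + r_hi))
    hfp = homogeneous_fixed_point(params, NeighborGraph.pair())
    return float(hfp.state[0, 2])


def init_crypt(config: CryptConfig, params: CircuitParams) -> CryptWorld:
    """Lay down the support stripe and seed the epithelial monolayer.

    Cells start at their reference volume in ``epithelial_rows`` rows of
    ``cell_size`` x ``cell_size`` squares directly on the support; their
    signaling states sit at the homogeneous fixed point with small seeded
    multiplicative noise, so the mosaic pattern emerges (or not) inside the
    running tissue.
    """
    H, W = config.height, config.width
    lattice = np.full((H, W), MEDIUM, dtype=np.int64)
    lattice[: config.support_rows, :] = SUPPORT
    n_cols = W // config.cell_size
    n_cells = n_cols * config.epithelial_rows
    cap = FIRST_CELL_ID + 4 * n_cells
    world = CryptWorld(
        config=config,
        params=params,
        lattice=lattice,
        cell_type=np.zeros(cap, dtype=np.int64),
        volumes=np.zeros(cap, dtype=np.int64),
        target_vol=np.zeros(cap),
        signaling=np.zeros((cap, 3)),
        alive=np.zeros(cap, dtype=bool),
        nicd_threshold=(
            config.nicd_threshold
            if config.nicd_threshold is not None
            else auto_nicd_threshold(params)
        ),
        energy=0.0,
    )
    world.cell_type[MEDIUM] = T_MEDIUM
    world.cell_type[SUPPORT] = T_SUPPORT

    ss = np.random.SeedSequence(config.seed)
    potts_ss, noise_ss, division_ss = ss.spawn(3)
    world._potts_seeds = potts_ss.generate_state(config.n_mcs + 1, dtype=np.uint32)
    world._division_rng = np.random.default_rng(division_ss)
    noise_rng = np.random.default_rng(noise_ss)

    hfp = homogeneous_fixed_point(params, NeighborGraph.pair())
    base_state = hfp.state[0]

    cid = FIRST_CELL_ID
    for layer in range(config.epithelial_rows):
        r0 = config.support_rows + layer * config.cell_size
        for col in range(n_cols):
            c0 = col * config.cell_size
            lattice[r0 : r0 + config.cell_size, c0 : c0 + config.cell_size] = cid
            world.volumes[cid] = config.cell_size**2
            world.target_vol[cid] = config.target_volume
            world.alive[cid] = True
            world.signaling[cid] = base_state * (
                1.0 + config.init_noise * noise_rng.uniform(-1.0, 1.0, size=3)
            )
            world.cell_type[cid] = (
                T_STEM if world.signaling[cid, 2] >= world.nicd_threshold else T_PANETH
            )
            cid += 1
    world.next_id = cid
    world.energy = world.recompute_energy()
    return world


def potts_step(world: CryptWorld) -> None:
    """One Monte-Carlo step of pixel-copy attempts (in place)."""
    seed = int(world._potts_seeds[world.mcs % len(world._potts_seeds)])
    dE = potts_mcs(
        world.lattice,
        world.cell_type,
        world.volumes,
        world.target_vol,
        world.config.J_table(),
        world.config.lambda_volume,
        world.config.potts_temperature,
        seed,
    )
    world.energy += dE


def niche_contact_graph(world: CryptWorld) -> tuple[np.ndarray, NeighborGraph, np.ndarray]:
    """Contact-length-weighted neighbor graph of the niche epithelial cells.

    Returns (cell ids, graph, support-contact lengths per id).  Weights are
    shared boundary length normalized per cell (juxtacrine signaling flux is
    proportional to contact area); cells without epithelial contact get an
    all-zero row (their neighbor means are 0).
    """
    C = contact_counts(world.lattice, world.next_id)
    ids = world.niche_cells()
    sub = C[np.ix_(ids, ids)].astype(float)
    np.fill_diagonal(sub, 0.0)
    rows = sub.sum(axis=1)
    W = np.divide(sub, rows[:, None], out=np.zeros_like(sub), where=rows[:, None] > 0)
    graph = NeighborGraph(W=W)
    return ids, graph, C[ids, SUPPORT]


def signaling_step(world: CryptWorld, n_substeps: int = 4) -> None:
    """Advance every niche cell's circuit ODEs by ``ode_dt`` (RK4).

    Neighbor means use contact-length weights over touching epithelial
    neighbors; a cell with no epithelial contact sees zero external ligand.
    Cells outside the niche zone are not integrated.
    """
    ids, graph, _sup = niche_contact_graph(world)
    if ids.size == 0:
        return
    y = world.signaling[ids].copy()
    dt = world.config.ode_dt / n_substeps
    Wm = graph.W
    for _ in range(n_substeps):
        y = _rk4_step(y, world.params, Wm, dt)
    if not np.all(np.isfinite(y)):
        bad = ids[~np.all(np.isfinite(y), axis=1)]
        raise RuntimeError(f"signaling integration failed for cells {bad.tolist()}")
    world.signaling[ids] = np.maximum(y, 0.0)


def _rk4_step(y: np.ndarray, params: CircuitParams, Wm: np.ndarray, dt: float) -> np.ndarray:
    # inlined MODEL3 right-hand side (hot path: called every MCS)
    bN, bD = params.beta_N, params.beta_D
    an, aD, aR = params.alpha_n, params.alpha_D, params.alpha_R
    kp, kd, p, h = params.k_p, params.k_d, params.p, params.h
    S_PF, S_LI = params.S_PF, params.S_LI

    def f(state):
        state = np.maximum(state, 0.0)
        N, D, R = state[:, 0], state[:, 1], state[:, 2]
        meanD = Wm @ D
        meanN = Wm @ N
        s = N * meanD
        tp = (s / kp) ** p
        th = (s / kd) ** h
        act = (1.0 - S_PF) + S_PF * tp / (1.0 + tp)
        rep = (1.0 - S_LI) + S_LI / (1.0 + th)
        return np.column_stack(
            [bN * act - an * N - s, bD * rep - aD * D - meanN * D, s - aR * R]
        )

    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def fate_update(world: CryptWorld) -> None:
    """Assign stem/Paneth fate by the NICD threshold and grow stem cells.

    NICD >= threshold (boundary inclusive) marks a Notch-high stem cell,
    whose target volume grows by ``growth_rate * turnover_multiplier`` per
    MCS; Notch-low Paneth cells neither grow nor divide.  Fate switches are
    logged.
    """
    cfg = world.config
    growth = cfg.growth_rate * cfg.turnover_multiplier
    for cid in world.live_cells():
        new_type = T_STEM if world.signaling[cid, 2] >= world.nicd_threshold else T_PANETH
        if not cfg.allow_reversion and world.cell_type[cid] == T_PANETH:
            new_type = T_PANETH
        if new_type != world.cell_type[cid]:
            world.log("fate_switch", cid, new_type=int(new_type))
            world.cell_type[cid] = new_type
        if world.cell_type[cid] == T_STEM:
            old = world.target_vol[cid]
            world.target_vol[cid] = old + growth
            v = world.volumes[cid]
            world.energy += cfg.lambda_volume * (
                (v - world.target_vol[cid]) ** 2 - (v - old) ** 2
            )


def _circular_centroid_col(cols: np.ndarray, width: int) -> float:
    """Centroid column of a possibly wrap-around pixel set."""
    ang = cols * (2.0 * np.pi / width)
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return (mean_ang * width / (2.0 * np.pi)) % width


def divide_cell(world: CryptWorld, cell_id: int, max_retries: int = 5) -> Optional[int]:
    """Split a cell along a random axis through its centroid.

    Daughters inherit the mother's signaling state and type; each receives
    half the mother's target volume.  Returns the new cell id, or None if
    no axis produced two nonempty halves within the retry budget.
    """
    px = np.argwhere(world.lattice == cell_id)
    if len(px) < 2:
        return None
    W = world.config.width
    cx = float(px[:, 0].mean())
    cy = _circular_centroid_col(px[:, 1], W)
    dcol = (px[:, 1] - cy + W / 2) % W - W / 2  # wrapped column offsets
    for _ in range(max_retries):
        theta = world._division_rng.uniform(0.0, 2.0 * np.pi)
        nvec = np.array([np.cos(theta), np.sin(theta)])
        side = (px[:, 0] - cx) * nvec[0] + dcol * nvec[1] > 0.0
        if side.any() and (~side).any():
            break
    else:
        return None
    new_id = world.next_id
    world._ensure_capacity(new_id)
    world.next_id += 1
    moved = px[side]
    world.lattice[moved[:, 0], moved[:, 1]] = new_id
    world.volumes[new_id] = len(moved)
    world.volumes[cell_id] -= len(moved)
    half = world.target_vol[cell_id] / 2.0
    world.target_vol[cell_id] = half
    world.target_vol[new_id] = half
    world.signaling[new_id] = world.signaling[cell_id]
    world.cell_type[new_id] = world.cell_type[cell_id]
    world.alive[new_id] = True
    world.log("division", cell_id, daughter=int(new_id))
    world.energy = world.recompute_energy()  # split line changes adhesion
    return new_id


def _remove_cell(world: CryptWorld, cell_id: int) -> None:
    world.lattice[world.lattice == cell_id] = MEDIUM
    world.alive[cell_id] = False
    world.volumes[cell_id] = 0
    world.cell_type[cell_id] = T_MEDIUM


def anoikis_and_exit(world: CryptWorld) -> None:
    """Remove cells leaving the niche zone (exit) and detached cells (anoikis).

    A cell displaced upward out of the monolayer band (or past
    ``niche_top``) has been pushed out of the crypt base by its growing and
    dividing neighbors and is removed at the domain edge -- in the full
    crypt it would migrate on up the wall.  A cell that lost all
    basement-membrane contact while still at monolayer height dies in place
    by anoikis.
    """
    rows = world.centroid_rows()
    C = contact_counts(world.lattice, world.next_id)
    cfg = world.config
    exit_row = min(cfg.support_rows + cfg.cell_size, cfg.niche_top)
    removed = False
    for cid in world.live_cells():
        r = rows.get(int(cid), 0.0)
        detached = C[cid, SUPPORT] == 0
        if r >= cfg.niche_top or (detached and r >= exit_row):
            world.log("exit", cid)
            _remove_cell(world, cid)
            removed = True
        elif detached:
            world.log("anoikis", cid)
            _remove_cell(world, cid)
            removed = True
    if removed:
        world.energy = world.recompute_energy()


@dataclass
class CryptRun:
    """Output of a crypt simulation."""

    world: CryptWorld
    samples: pd.DataFrame          # (mcs, cell_id, nicd, type)
    events: pd.DataFrame           # (mcs, event, cell_id, ...)
    snapshots: list[np.ndarray]    # integer-labeled lattices

    def event_counts(self) -> dict[str, int]:
        if self.events.empty:
            return {"division": 0, "anoikis": 0, "exit": 0}
        counts = self.events["event"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("division", "anoikis", "exit")}

    def final_nicd(self) -> np.ndarray:
        last = self.samples["mcs"].max()
        return self.samples.loc[self.samples["mcs"] == last, "nicd"].to_numpy()

    def window_nicd(self, frac: float = 1.0 / 3.0) -> np.ndarray:
        """NICD samples pooled over the trailing ``frac`` of the run.

        Pooling sampled time points captures cells transiting between the
        high and low modes (the blur of a disrupted pattern), which a single
        final snapshot can miss.
        """
        cut = self.samples["mcs"].max() * (1.0 - frac)
        return self.samples.loc[self.samples["mcs"] >= cut, "nicd"].to_numpy()

    def final_bimodality(self) -> float:
        return bimodality(self.final_nicd())

    def window_bimodality(self, frac: float = 1.0 / 3.0) -> float:
        return bimodality(self.window_nicd(frac))

    def final_checkerboard(self) -> float:
        world = self.world
        ids, graph, _ = niche_contact_graph(world)
        labels = (world.signaling[ids, 2] >= world.nicd_threshold).astype(int)
        return checkerboard_score(labels, graph)


def run_crypt(
    config: CryptConfig,
    params: CircuitParams,
    n_mcs: Optional[int] = None,
    freeze_mechanics: bool = False,
    snapshot_every: Optional[int] = None,
) -> CryptRun:
    """Simulate the crypt for ``n_mcs`` Monte-Carlo steps.

    Per MCS: pixel-copy mechanics, signaling integration, fate update and
    stem-cell growth, divisions, then anoikis/exit removal; NICD of all
    niche cells is sampled every ``sample_every`` MCS.  The run is fully
    reproducible from ``config.seed``.  With ``freeze_mechanics`` the
    lattice is static and only signaling advances (used to check that the
    tissue ODEs reduce to the lattice-ODE dynamics on the contact graph).
    """
    n_mcs = config.n_mcs if n_mcs is None else n_mcs
    world = init_crypt(config, params)
    samples: list[dict] = []
    snapshots: list[np.ndarray] = []

    def sample_now() -> None:
        for cid in world.niche_cells():
            samples.append(
                {
                    "mcs": world.mcs,
                    "cell_id": int(cid),
                    "nicd": float(world.signaling[cid, 2]),
                    "type": "stem" if world.cell_type[cid] == T_STEM else "paneth",
                }
            )

    sample_now()
    for _ in range(n_mcs):
        world.mcs += 1
        if not freeze_mechanics:
            potts_step(world)
        for _k in range(config.mcs_per_ode_step):
            signaling_step(world)
        if not freeze_mechanics:
            fate_update(world)
            for cid in list(world.live_cells()):
                if (
                    world.cell_type[cid] == T_STEM
                    and world.volumes[cid] >= config.division_volume
                ):
                    divide_cell(world, cid)
            anoikis_and_exit(world)
        if world.mcs % config.sample_every == 0:
            sample_now()
        if snapshot_every and world.mcs % snapshot_every == 0:
            snapshots.append(world.lattice.copy())
    snapshots.append(world.lattice.copy())
    return CryptRun(
        world=world,
        samples=pd.DataFrame(samples),
        events=pd.DataFrame(world.events),
        snapshots=snapshots,
    )


def _suppressed_circuit(params: CircuitParams, s_pf: float, mode: str) -> CircuitParams:
    """Circuit with the positive feedback reduced to strength ``s_pf``.

    ``mode="rescale"`` swaps regulated for basal production at a fixed
    production budget (``S_PF`` replaced, ``beta_N`` unchanged); ``s_pf = 0``
    is then exactly the pure-LI circuit.  ``mode="knockdown"`` emulates the
    genetic perturbation of the feedback enhancer: ``s_pf`` is the retained
    fraction of the PF-regulated transcription, the basal production
    ``beta_N (1 - S_PF)`` is kept, so total Notch production falls as the
    feedback is lost.  The two modes coincide at ``s_pf = 1`` only for
    knockdown (full circuit).
    """
    if not 0.0 <= s_pf <= 1.0:
        raise ValueError("S_PF values must lie in [0, 1]")
    if mode == "rescale":
        return params.with_(S_PF=float(s_pf))
    if mode != "knockdown":
        raise ValueError("mode must be 'rescale' or 'knockdown'")
    basal = params.beta_N * (1.0 - params.S_PF)
    regulated = s_pf * params.beta_N * params.S_PF
    beta_N = basal + regulated
    return params.with_(beta_N=beta_N, S_PF=regulated / beta_N)


def pf_strength_sweep(
    config: CryptConfig,
    params: CircuitParams,
    s_pf_values: Sequence[float],
    seeds: Sequence[int],
    mode: str = "rescale",
) -> pd.DataFrame:
    """Crypt runs across positive-feedback strengths.

    For each ``S_PF`` and seed, reports the fraction of niche cells in the
    NICD-high mode and the mean NICD of that mode at the end of the run.
    The NICD threshold of the reference circuit is used throughout so that
    fractions are comparable across ``S_PF``.  See
    :func:`_suppressed_circuit` for the two suppression protocols.
    """
    ref_threshold = (
        config.nicd_threshold
        if config.nicd_threshold is not None
        else auto_nicd_threshold(params)
    )
    rows = []
    for s_pf in s_pf_values:
        p = _suppressed_circuit(params, float(s_pf), mode)
        for seed in seeds:
            cfg = dataclasses.replace(config, seed=int(seed), nicd_threshold=ref_threshold)
            run = run_crypt(cfg, p)
            nicd = run.final_nicd()
            high = nicd >= ref_threshold
            rows.append(
                {
                    "S_PF": float(s_pf),
                    "seed": int(seed),
                    "high_fraction": float(high.mean()) if nicd.size else float("nan"),
                    "high_mean_nicd": float(nicd[high].mean()) if high.any() else 0.0,
                    "n_cells": int(nicd.size),
                }
            )
    return pd.DataFrame(rows)
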
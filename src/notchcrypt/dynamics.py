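"""Steady-state and bifurcation analysis of single- and pair-cell circuits.

The single-cell protocol presents an external ligand level ``D_ext`` to one
cell (``<D_j> = D_ext``, ``<N_j> = 0``); its NOTCH equation decouples, so
every fixed point is found exactly by sign-change bracketing of a 1-D
self-consistency function.  Pure lateral inhibition gives a single branch
that decreases monotonically with ``D_ext``; adding the Notch positive
feedback can fold the branch into an S-shaped hysteresis loop.

The pair-cell analysis finds all fixed points of two mutually coupled cells
by deterministic multi-start root finding and classifies them by the
Jacobian spectrum; lateral inhibition alone needs a higher ligand-repression
Hill coefficient ``h`` to achieve the bistability (Notch-high vs Notch-low
neighbors) that the positive feedback obtains already at low cooperativity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .circuits import (
    CircuitParams,
    ModelForm,
    Stimulus,
    hill_activation,
    hill_repression,
    jacobian_model3,
    rhs_model3,
)
from .lattice import NeighborGraph

__all__ = [
    "Stability",
    "SteadyState",
    "BifurcationBranch",
    "HysteresisReport",
    "PhasePortrait",
    "classify_stability",
    "single_cell_response",
    "detect_hysteresis",
    "pair_fixed_points",
    "pair_bistability_map",
    "minimum_bistable_h",
    "nullclines",
]

_EIG_MARGIN = 1e-9  # eigenvalues closer to the axis are flagged marginal


class Stability(Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    SADDLE = "saddle"


@dataclass
class SteadyState:
    """A fixed point with its Jacobian spectrum and stability class.

    ``state`` is (n_cells, 3) for MODEL3 systems.  Points with an eigenvalue
    real part within ``1e-9`` of zero are classified UNSTABLE and flagged
    ``marginal`` (conservative: near-marginal states are not counted as
    patterned/stable).
    """

    state: np.ndarray
    jacobian_eigs: np.ndarray
    stability: Stability
    residual: float
    marginal: bool = False

    @property
    def is_stable(self) -> bool:
        return self.stability is Stability.STABLE


def _require_model3(params: CircuitParams) -> None:
    if params.model_form is not ModelForm.MODEL3:
        raise ValueError(
            "steady-state analyses run on the protein-only MODEL3 form; "
            "reduce MODEL2 parameters with qssa_reduce first"
        )


def classify_stability(
    state: np.ndarray,
    params: CircuitParams,
    graph: NeighborGraph,
    stimulus: Stimulus | None = None,
    residual_tol: float = 1e-8,
) -> SteadyState:
    """Classify a candidate fixed point by its Jacobian eigenvalues.

    STABLE: all real parts < 0; UNSTABLE: all > 0; SADDLE: mixed signs.
    Raises if the RHS residual at the point exceeds ``residual_tol``.
    """
    _require_model3(params)
    state = np.atleast_2d(np.asarray(state, dtype=float))
    d_ext = stimulus.D_ext if stimulus else 0.0
    n_ext = stimulus.N_ext if stimulus else 0.0
    meanD = graph.W @ state[:, 1] + d_ext
    meanN = graph.W @ state[:, 0] + n_ext
    res = float(np.max(np.abs(rhs_model3(state, params, meanD, meanN))))
    if res > residual_tol:
        raise ValueError(f"not a fixed point: RHS residual {res:.3e} > {residual_tol:.1e}")
    J = jacobian_model3(state, params, graph.W, stimulus)
    eigs = np.linalg.eigvals(J)
    re = eigs.real
    marginal = bool(np.any(np.abs(re) <= _EIG_MARGIN))
    if marginal:
        stab = Stability.UNSTABLE
    elif np.all(re < 0):
        stab = Stability.STABLE
    elif np.all(re > 0):
        stab = Stability.UNSTABLE
    else:
        stab = Stability.SADDLE
    return SteadyState(state=state, jacobian_eigs=eigs, stability=stab, residual=res, marginal=marginal)


# ---------------------------------------------------------------------------
# Single-cell input--output analysis
# ---------------------------------------------------------------------------

def _single_cell_notch_residual(N: np.ndarray, params: CircuitParams, d_ext: float):
    """f(N) whose roots are the single-cell NOTCH fixed points at D_ext."""
    s = N * d_ext
    act = (1.0 - params.S_PF) + params.S_PF * hill_activation(s, params.k_p, params.p)
    return params.beta_N * act - (params.alpha_n + d_ext) * N


def _single_cell_fixed_points(
    params: CircuitParams, d_ext: float, n_scan: int = 2000
) -> list[np.ndarray]:
    """All fixed points at one D_ext by dense 1-D bracketing in N."""
    n_max = 1.05 * params.beta_N / params.alpha_n
    grid = np.linspace(0.0, n_max, n_scan)
    f = _single_cell_notch_residual(grid, params, d_ext)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0:
            roots.append(grid[i])
        elif f[i] * f[i + 1] < 0:
            r = optimize.brentq(
                lambda N: _single_cell_notch_residual(np.asarray(N), params, d_ext),
                grid[i],
                grid[i + 1],
                xtol=1e-14,
                rtol=1e-14,
            )
            roots.append(float(r))
    if f[-1] == 0.0:
        roots.append(grid[-1])
    out = []
    for N in sorted(set(roots)):
        s = N * d_ext
        rep = (1.0 - params.S_LI) + params.S_LI * hill_repression(s, params.k_d, params.h)
        D = params.beta_D * rep / params.alpha_D
        R = s / params.alpha_R
        out.append(np.array([[N, D, R]]))
    return out


@dataclass
class BifurcationBranch:
    """Fixed points of the single-cell system along a D_ext grid.

    ``points[i]`` lists the :class:`SteadyState` objects at ``d_ext[i]``;
    ``fold_points`` holds the D_ext values (midpoints of the bracketing grid
    cells) where the number of fixed points changes.
    """

    d_ext: np.ndarray
    points: list[list[SteadyState]]
    fold_points: list[float] = field(default_factory=list)

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(p.is_stable for p in pts) for pts in self.points])

    def stable_internal_D(self) -> list[np.ndarray]:
        """Stable-branch internal DLL values per grid point."""
        return [np.array([p.state[0, 1] for p in pts if p.is_stable]) for pts in self.points]


def single_cell_response(
    params: CircuitParams, d_ext_grid: Sequence[float]
) -> BifurcationBranch:
    """Fixed points and stability of one cell exposed to external ligand.

    ``<D_j>`` is set to each ``D_ext`` in turn with ``<N_j> = 0`` (the
    standard protocol: external receptor is absent, so the cell's own ligand
    is not trans-depleted).
    """
    _require_model3(params)
    d_ext_grid = np.asarray(d_ext_grid, dtype=float)
    if np.any(d_ext_grid < 0) or np.any(np.diff(d_ext_grid) <= 0):
        raise ValueError("d_ext_grid must be nonnegative and strictly increasing")
    graph = NeighborGraph(W=np.zeros((1, 1)))
    points: list[list[SteadyState]] = []
    for d_ext in d_ext_grid:
        stim = Stimulus(D_ext=float(d_ext))
        here = []
        for st in _single_cell_fixed_points(params, float(d_ext)):
            try:
                here.append(classify_stability(st, params, graph, stim))
            except ValueError as exc:  # pragma: no cover - root refinement failed
                warnings.warn(f"skipping point at D_ext={d_ext}: {exc}")
        points.append(here)
    counts = np.array([len(p) for p in points])
    folds = [
        float(0.5 * (d_ext_grid[i] + d_ext_grid[i + 1]))
        for i in range(len(counts) - 1)
        if counts[i] != counts[i + 1]
    ]
    return BifurcationBranch(d_ext=d_ext_grid, points=points, fold_points=folds)


@dataclass
class HysteresisReport:
    """Bistable D_ext window of a single-cell branch (or none)."""

    window: Optional[tuple[float, float]]
    fold_points: list[float]

    @property
    def is_bistable(self) -> bool:
        return self.window is not None

    @property
    def width(self) -> float:
        return 0.0 if self.window is None else self.window[1] - self.window[0]


def detect_hysteresis(branch: BifurcationBranch) -> HysteresisReport:
    """Maximal D_ext interval of the branch carrying >= 2 stable fixed points."""
    counts = branch.stable_counts()
    idx = np.flatnonzero(counts >= 2)
    if idx.size == 0:
        return HysteresisReport(window=None, fold_points=branch.fold_points)
    window = (float(branch.d_ext[idx[0]]), float(branch.d_ext[idx[-1]]))
    return HysteresisReport(window=window, fold_points=branch.fold_points)


# ---------------------------------------------------------------------------
# Pair-cell analysis
# ---------------------------------------------------------------------------

def _pair_rhs_flat(yflat: np.ndarray, params: CircuitParams, W: np.ndarray) -> np.ndarray:
    y = np.maximum(yflat.reshape(3, 2).T, 0.0)
    meanD = W @ y[:, 1]
    meanN = W @ y[:, 0]
    return rhs_model3(y, params, meanD, meanN).T.ravel()


def pair_fixed_points(
    params: CircuitParams,
    n_starts: int = 64,
    dedupe_rtol: float = 1e-6,
    residual_tol: float = 1e-9,
) -> list[SteadyState]:
    """All fixed points of two mutually coupled cells.

    Deterministic multi-start Newton--hybrid root finding from an
    unscrambled Sobol' design spanning ``[0, 2 beta/alpha]`` per species,
    augmented with warm starts obtained by integrating from symmetric and
    strongly asymmetric initial conditions (these land in every attracting
    basin, so no stable state is missed); converged roots are merged at
    ``dedupe_rtol`` relative distance and completed under the swap symmetry.
    The exchange symmetry of the pair guarantees a symmetric fixed point;
    asymmetric points occur in swap-symmetric pairs.
    """
    from .integrate import integrate  # local import to avoid a cycle

    _require_model3(params)
    graph = NeighborGraph.pair()
    W = graph.W
    n_hi = params.beta_N / params.alpha_n
    d_hi = params.beta_D / params.alpha_D
    r_hi = n_hi * d_hi / params.alpha_R
    scales = np.array([n_hi, d_hi, r_hi])
    sob = qmc.Sobol(d=6, scramble=False)
    # columns of the flat state are (N1, N2, D1, D2, R1, R2)
    starts = 2.0 * sob.random(n_starts) * np.repeat(scales, 2)[None, :]
    warm_ics = [
        np.array([[0.5 * n_hi, 0.5 * d_hi, 0.0], [0.5 * n_hi, 0.5 * d_hi, 0.0]]),
        np.array([[n_hi, 1e-3 * d_hi, 0.0], [1e-3 * n_hi, d_hi, 0.0]]),
        np.array([[1e-3 * n_hi, 1e-2 * d_hi, 0.0], [1e-2 * n_hi, 1e-3 * d_hi, 0.0]]),
        np.array([[n_hi, d_hi, 0.0], [0.5 * n_hi, 0.5 * d_hi, 0.0]]),
    ]
    extra = []
    for y0 in warm_ics:
        try:
            traj = integrate(params, y0, graph, 400.0, t_eval=np.array([0.0, 400.0]))
            extra.append(traj.final.T.ravel())
        except Exception:  # pragma: no cover - warm start is best-effort
            pass

    def _try_root(x0: np.ndarray) -> Optional[np.ndarray]:
        sol = optimize.root(_pair_rhs_flat, x0, args=(params, W), method="hybr", tol=1e-12)
        if not sol.success:
            return None
        x = np.maximum(sol.x, 0.0)
        if np.max(np.abs(_pair_rhs_flat(x, params, W))) > residual_tol:
            return None
        return x

    def _is_new(x: np.ndarray, roots: list[np.ndarray]) -> bool:
        return not any(
            np.allclose(x, r, rtol=0, atol=dedupe_rtol * (np.abs(scales).max() + np.abs(r).max()))
            for r in roots
        )

    roots: list[np.ndarray] = []
    for x0 in list(starts) + extra:
        x = _try_root(x0)
        if x is not None and _is_new(x, roots):
            roots.append(x)
    # complete under cell-exchange symmetry: if (x, y) is a root so is (y, x)
    for x in list(roots):
        swapped = x.reshape(3, 2)[:, ::-1].ravel()
        xs = _try_root(swapped)
        if xs is not None and _is_new(xs, roots):
            roots.append(xs)
    out = []
    for x in roots:
        state = x.reshape(3, 2).T
        out.append(classify_stability(state, params, graph, residual_tol=1e-7))
    out.sort(key=lambda ss: (round(float(ss.state[:, 0].sum()), 9), float(ss.state[0, 0])))
    return out


def pair_bistability_map(
    params: CircuitParams,
    h_values: Sequence[float],
    p_values: Sequence[float],
) -> np.ndarray:
    """Boolean matrix: does the pair have >= 2 stable fixed points at (h, p)?

    Rows index ``h_values``, columns ``p_values`` (``p`` is irrelevant when
    ``S_PF = 0``; the column is then constant).
    """
    out = np.zeros((len(h_values), len(p_values)), dtype=bool)
    for i, h in enumerate(h_values):
        for j, p in enumerate(p_values):
            pts = pair_fixed_points(params.with_(h=float(h), p=float(p)))
            out[i, j] = sum(ss.is_stable for ss in pts) >= 2
    return out


def minimum_bistable_h(
    params: CircuitParams, h_values: Sequence[float], p: Optional[float] = None
) -> Optional[float]:
    """Smallest h in ``h_values`` at which the pair is bistable (None if never)."""
    p = params.p if p is None else p
    for h in sorted(h_values):
        pts = pair_fixed_points(params.with_(h=float(h), p=float(p)))
        if sum(ss.is_stable for ss in pts) >= 2:
            return float(h)
    return None


# ---------------------------------------------------------------------------
# Phase portraits
# ---------------------------------------------------------------------------

@dataclass
class PhasePortrait:
    """Nullclines of the pair system in a 2-D projection.

    ``f1_grid``/``f2_grid`` hold the two reduced rate functions evaluated on
    the (axis1, axis2) grid; their zero contours are the nullclines.  The
    remaining species are eliminated by their own steady-state relations.
    """

    axis_species: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    f1_grid: np.ndarray
    f2_grid: np.ndarray
    nullclines: tuple[list[np.ndarray], list[np.ndarray]]
    fixed_points: list[SteadyState]
    hill_pair: tuple[float, float]


def _qss_pair_D(params: CircuitParams, N1: float, N2: float, iters: int = 200) -> tuple[float, float]:
    """Ligand levels at quasi-steady state given the two NOTCH levels."""
    D1 = params.beta_D / params.alpha_D
    D2 = D1
    for _ in range(iters):
        rep1 = (1.0 - params.S_LI) + params.S_LI * hill_repression(N1 * D2, params.k_d, params.h)
        rep2 = (1.0 - params.S_LI) + params.S_LI * hill_repression(N2 * D1, params.k_d, params.h)
        D1n = params.beta_D * rep1 / (params.alpha_D + N2)
        D2n = params.beta_D * rep2 / (params.alpha_D + N1)
        if abs(D1n - D1) + abs(D2n - D2) < 1e-13 * (1.0 + D1 + D2):
            D1, D2 = D1n, D2n
            break
        # damped update keeps the iteration contractive at strong repression
        D1 = 0.5 * D1 + 0.5 * D1n
        D2 = 0.5 * D2 + 0.5 * D2n
    return D1, D2


def _zero_contour(x: np.ndarray, y: np.ndarray, F: np.ndarray) -> list[np.ndarray]:
    """Points on the zero level set of F, located by linear interpolation
    along grid edges (enough to test membership; not a curve tracer)."""
    pts = []
    for i in range(F.shape[0]):
        for j in range(F.shape[1] - 1):
            a, b = F[i, j], F[i, j + 1]
            if a == 0.0:
                pts.append((x[i], y[j]))
            elif a * b < 0:
                t = a / (a - b)
                pts.append((x[i], y[j] + t * (y[j + 1] - y[j])))
    for j in range(F.shape[1]):
        for i in range(F.shape[0] - 1):
            a, b = F[i, j], F[i + 1, j]
            if a * b < 0:
                t = a / (a - b)
                pts.append((x[i] + t * (x[i + 1] - x[i]), y[j]))
    return [np.array(p) for p in pts]


def nullclines(
    params: CircuitParams,
    projection: tuple[str, str] = ("N_i", "N_j"),
    grid: Optional[np.ndarray] = None,
) -> PhasePortrait:
    """Pair-cell nullclines in the (N_i, N_j) projection.

    The ligands are eliminated at quasi-steady state given (N_i, N_j); the
    two plotted rate functions are the NOTCH balance equations of the two
    cells.  All pair fixed points lie on both zero contours.
    """
    _require_model3(params)
    if tuple(projection) != ("N_i", "N_j"):
        raise ValueError("only the (N_i, N_j) projection is implemented")
    if grid is None:
        grid = np.linspace(1e-6, 1.5 * params.beta_N / params.alpha_n, 81)
    grid = np.asarray(grid, dtype=float)
    F1 = np.zeros((len(grid), len(grid)))
    F2 = np.zeros_like(F1)
    for i, N1 in enumerate(grid):
        for j, N2 in enumerate(grid):
            D1, D2 = _qss_pair_D(params, N1, N2)
            act1 = (1.0 - params.S_PF) + params.S_PF * hill_activation(N1 * D2, params.k_p, params.p)
            act2 = (1.0 - params.S_PF) + params.S_PF * hill_activation(N2 * D1, params.k_p, params.p)
            F1[i, j] = params.beta_N * act1 - params.alpha_n * N1 - N1 * D2
            F2[i, j] = params.beta_N * act2 - params.alpha_n * N2 - N2 * D1
    fps = pair_fixed_points(params)
    return PhasePortrait(
        axis_species=("N_i", "N_j"),
        axis1=grid,
        axis2=grid,
        f1_grid=F1,
        f2_grid=F2,
        nullclines=(_zero_contour(grid, grid, F1), _zero_contour(grid, grid, F2)),
        fixed_points=fps,
        hill_pair=(params.h, params.p),
    )
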
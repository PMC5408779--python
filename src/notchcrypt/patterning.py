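"""Multicell patterning analysis: linear stability and dynamics.

Patterning competence of a circuit on a lattice is assessed by the maximum
Lyapunov exponent (MLE): the largest real part over the spectrum of the
multicell Jacobian linearized at the spatially homogeneous steady state.  A
positive MLE means some nonuniform perturbation mode grows, so lateral
inhibition can amplify cell-to-cell differences into a mosaic
(checkerboard-like) pattern of Notch-high and Notch-low cells; a negative
MLE means the uniform state is an attractor and no pattern forms.

Deterministic patterning runs start from the homogeneous state with small
multiplicative noise and are integrated to a heterogeneous steady state;
the time at which the ligand change rate last falls below a threshold
defines the end of the patterning transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .circuits import (
    CircuitParams,
    ModelForm,
    hill_activation,
    hill_repression,
    jacobian_model3,
    rhs_model3,
)
from .dynamics import SteadyState, classify_stability
from .integrate import IntegrationError, Trajectory, integrate, multicell_rhs_flat
from .lattice import NeighborGraph
from .stats import two_means_split

__all__ = [
    "DEFAULT_BETA_N_GRID",
    "DEFAULT_BETA_D_GRID",
    "MLEMap",
    "PatterningRun",
    "homogeneous_fixed_point",
    "compute_mle",
    "mle_sweep",
    "simulate_patterning",
    "pattern_time",
    "match_notch_levels",
]


def _require_model3(params: CircuitParams) -> None:
    if params.model_form is not ModelForm.MODEL3:
        raise ValueError("patterning analyses run on MODEL3 parameters")


#: Default production-rate sweep. Notch production spans the default
#: operating rate up to ~6x (below the default rate the receptor supply
#: cannot sustain signaling in either circuit); ligand production spans
#: weak to strong presentation.
DEFAULT_BETA_N_GRID = np.linspace(4.0, 23.0, 20)
DEFAULT_BETA_D_GRID = np.linspace(1.0, 20.0, 20)


def _uniform_ligand_level(params: CircuitParams, N: np.ndarray) -> np.ndarray:
    """Uniform-state ligand level D(N): unique root of the D balance.

    At a uniform state ``<D_j> = D`` and ``<N_j> = N``, so D solves
    ``beta_D G(N D) = (alpha_D + N) D`` with G the (partially) repressed
    production.  The right side grows in D while G falls, so the root is
    unique; a damped Picard iteration converges for all parameter values.
    """
    N = np.asarray(N, dtype=float)
    D = np.full_like(N, params.beta_D / params.alpha_D)
    for _ in range(400):
        rep = (1.0 - params.S_LI) + params.S_LI * np.asarray(
            hill_repression(N * D, params.k_d, params.h)
        )
        Dn = params.beta_D * rep / (params.alpha_D + N)
        step = 0.5 * (Dn - D)
        D = D + step
        if np.max(np.abs(step)) < 1e-14 * (1.0 + np.max(D)):
            break
    return D


def homogeneous_fixed_points(
    params: CircuitParams, residual_tol: float = 1e-10, n_scan: int = 800
) -> list[np.ndarray]:
    """All spatially uniform fixed points (N, D, R), found exhaustively.

    Eliminating D by :func:`_uniform_ligand_level` reduces the uniform-state
    condition to a 1-D equation in N, whose roots are located by dense
    sign-change bracketing and Newton refinement of the full (N, D) system.
    """
    _require_model3(params)
    n_max = 1.05 * params.beta_N / params.alpha_n
    grid = np.linspace(0.0, n_max, n_scan)
    D = _uniform_ligand_level(params, grid)
    s = grid * D
    act = (1.0 - params.S_PF) + params.S_PF * np.asarray(
        hill_activation(s, params.k_p, params.p)
    )
    phi = params.beta_N * act - params.alpha_n * grid - s

    def f2(x):
        x = np.maximum(x, 0.0)
        N, Dv = x
        rep = (1.0 - params.S_LI) + params.S_LI * hill_repression(N * Dv, params.k_d, params.h)
        a = (1.0 - params.S_PF) + params.S_PF * hill_activation(N * Dv, params.k_p, params.p)
        return np.array(
            [
                params.beta_N * a - params.alpha_n * N - N * Dv,
                params.beta_D * rep - params.alpha_D * Dv - N * Dv,
            ]
        )

    points: list[np.ndarray] = []
    brackets = [i for i in range(n_scan - 1) if phi[i] == 0.0 or phi[i] * phi[i + 1] < 0]
    for i in brackets:
        sol = optimize.root(f2, np.array([grid[i], D[i]]), method="hybr", tol=1e-13)
        x = np.maximum(sol.x, 0.0)
        if np.max(np.abs(f2(x))) > residual_tol:
            continue
        N, Dv = x
        point = np.array([N, Dv, N * Dv / params.alpha_R])
        if not any(np.allclose(point, q, rtol=1e-7, atol=1e-10) for q in points):
            points.append(point)
    if not points:
        raise IntegrationError("no homogeneous fixed point found")
    return sorted(points, key=lambda q: q[0])


def _uniform_mle(params: CircuitParams, point: np.ndarray, graph: NeighborGraph) -> float:
    A, B = _mode_blocks(params, point)
    mus = np.linalg.eigvals(graph.W)
    return max(float(np.max(np.linalg.eigvals(A + mu * B).real)) for mu in mus)


def homogeneous_fixed_point(
    params: CircuitParams, graph: NeighborGraph, residual_tol: float = 1e-9
) -> SteadyState:
    """The patterning-relevant uniform steady state of the lattice system.

    When the uniform dynamics are multistable, the uniform state with the
    largest lattice MLE is returned: patterning competence means *some*
    homogeneous steady state is laterally unstable, and the deterministic
    patterning protocol perturbs exactly that state.  Stability in the
    returned object refers to the full lattice Jacobian, so SADDLE /
    UNSTABLE signals lateral (patterning) instability of the uniform state.
    """
    points = homogeneous_fixed_points(params, residual_tol=max(residual_tol, 1e-10))
    best = max(points, key=lambda q: _uniform_mle(params, q, graph))
    uniform = np.tile(best, (graph.n_cells, 1))
    return classify_stability(uniform, params, graph, residual_tol=max(residual_tol, 1e-7))


def compute_mle(
    params: CircuitParams,
    graph: NeighborGraph,
    method: str = "dense",
    hfp: Optional[SteadyState] = None,
) -> float:
    """Maximum Lyapunov exponent of the lattice at the homogeneous state.

    ``method="dense"`` takes the largest eigenvalue real part of the full
    (3n x 3n) multicell Jacobian.  ``method="modes"`` exploits the structure
    of neighbor-mean coupling: the Jacobian decomposes over eigenvalues
    ``mu`` of the weight matrix ``W`` into 3x3 blocks ``A + mu B``, which is
    exact for any uniform state and much faster for sweeps.  A positive MLE
    marks patterning competence.
    """
    _require_model3(params)
    if hfp is not None:
        if method == "dense":
            return float(np.max(hfp.jacobian_eigs.real))
        if method != "modes":
            raise ValueError("method must be 'dense' or 'modes'")
        return _uniform_mle(params, hfp.state[0], graph)
    points = homogeneous_fixed_points(params)
    mles = [_uniform_mle(params, q, graph) for q in points]
    best = float(max(mles))
    if method == "modes":
        return best
    if method != "dense":
        raise ValueError("method must be 'dense' or 'modes'")
    point = points[int(np.argmax(mles))]
    uniform = np.tile(point, (graph.n_cells, 1))
    J = jacobian_model3(uniform, params, graph.W)
    return float(np.max(np.linalg.eigvals(J).real))


def _mode_blocks(params: CircuitParams, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode 3x3 Jacobian blocks at a uniform state.

    At a uniform state the lattice Jacobian is ``I (x) A + W (x) B``: A
    collects the cell-local derivatives (neighbor means held fixed at their
    uniform values) and B the derivatives through the neighbor means.
    """
    from .circuits import hill_activation_deriv, hill_repression_deriv

    N, D, _R = point
    s = N * D
    a = params.beta_N * params.S_PF * hill_activation_deriv(s, params.k_p, params.p) - 1.0
    g = params.beta_D * params.S_LI * hill_repression_deriv(s, params.k_d, params.h)
    A = np.array(
        [
            [a * D - params.alpha_n, 0.0, 0.0],
            [g * D, -(params.alpha_D + N), 0.0],
            [D, 0.0, -params.alpha_R],
        ]
    )
    B = np.array(
        [
            [0.0, a * N, 0.0],
            [-D, g * N, 0.0],
            [0.0, N, 0.0],
        ]
    )
    return A, B


@dataclass
class MLEMap:
    """MLE values over a (beta_N, beta_D) production-rate grid."""

    beta_N_grid: np.ndarray
    beta_D_grid: np.ndarray
    H: float
    circuit: str
    mle: np.ndarray

    @property
    def pattern_mask(self) -> np.ndarray:
        return self.mle > 0

    @property
    def patterned_fraction(self) -> float:
        valid = np.isfinite(self.mle)
        return float(self.pattern_mask[valid].mean()) if valid.any() else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        bN, bD = np.meshgrid(self.beta_N_grid, self.beta_D_grid, indexing="ij")
        return pd.DataFrame(
            {
                "beta_N": bN.ravel(),
                "beta_D": bD.ravel(),
                "H": self.H,
                "circuit": self.circuit,
                "mle": self.mle.ravel(),
                "patterned": self.pattern_mask.ravel(),
            }
        )


def mle_sweep(
    base_params: CircuitParams,
    graph: NeighborGraph,
    beta_N_grid: Sequence[float],
    beta_D_grid: Sequence[float],
    H_values: Sequence[float] = (1.0, 2.0, 4.0),
    s_pf_values: Optional[Sequence[float]] = None,
) -> list[MLEMap]:
    """MLE maps over production rates, cooperativity H, and circuit variant.

    ``H`` is the cooperativity of the lateral-inhibition reaction (the
    ligand-repression Hill coefficient ``h``); the positive-feedback
    cooperativity ``p`` stays at its base value, since the two are distinct
    knobs of the circuit.  ``s_pf_values`` defaults to (0, base S_PF), i.e.
    the pure-LI circuit and the PFLI circuit.  Failed grid entries are
    recorded as NaN rather than aborting the sweep.
    """
    _require_model3(base_params)
    if s_pf_values is None:
        s_pf_values = (0.0, base_params.S_PF)
    beta_N_grid = np.asarray(beta_N_grid, dtype=float)
    beta_D_grid = np.asarray(beta_D_grid, dtype=float)
    if np.any(beta_N_grid <= 0) or np.any(beta_D_grid <= 0):
        raise ValueError("production-rate grids must be positive")
    maps = []
    for s_pf in s_pf_values:
        circuit = "li" if s_pf == 0 else "pfli"
        for H in H_values:
            mle = np.full((len(beta_N_grid), len(beta_D_grid)), np.nan)
            for i, bN in enumerate(beta_N_grid):
                for j, bD in enumerate(beta_D_grid):
                    p = base_params.with_(
                        beta_N=float(bN), beta_D=float(bD), h=float(H),
                        S_PF=float(s_pf),
                    )
                    try:
                        mle[i, j] = compute_mle(p, graph, method="modes")
                    except (IntegrationError, ValueError):
                        pass
            maps.append(
                MLEMap(beta_N_grid=beta_N_grid, beta_D_grid=beta_D_grid,
                       H=float(H), circuit=circuit, mle=mle)
            )
    return maps


@dataclass
class PatterningRun:
    """A seeded deterministic patterning simulation."""

    trajectory: Trajectory
    seed: int
    init_noise: float
    high_set: np.ndarray
    low_set: np.ndarray
    split_boundary: float
    converged: bool

    @property
    def final_R(self) -> np.ndarray:
        return self.trajectory.final[:, 2]

    def high_low_labels(self) -> np.ndarray:
        labels = np.zeros(self.trajectory.graph.n_cells, dtype=int)
        labels[self.high_set] = 1
        return labels


def simulate_patterning(
    params: CircuitParams,
    graph: NeighborGraph,
    seed: int,
    init_noise: float = 0.01,
    t_end: float = 200.0,
    n_samples: int = 801,
    residual_tol: float = 1e-6,
) -> PatterningRun:
    """Integrate the lattice from the noisy homogeneous state.

    The initial condition is the homogeneous fixed point multiplied
    per-species and per-cell by ``1 + init_noise * U(-1, 1)`` from a seeded
    generator.  Final cells are partitioned into NICD-high and NICD-low sets
    by a deterministic 1-D 2-means split; ``converged`` records whether the
    final state is a fixed point of the lattice RHS within ``residual_tol``.
    """
    hfp = homogeneous_fixed_point(params, graph)
    rng = np.random.default_rng(seed)
    y0 = hfp.state * (1.0 + init_noise * rng.uniform(-1.0, 1.0, size=hfp.state.shape))
    t_eval = np.linspace(0.0, t_end, n_samples)
    traj = integrate(params, y0, graph, t_end, t_eval=t_eval)
    final = traj.final
    f = multicell_rhs_flat(params, graph)
    res = float(np.max(np.abs(f(0.0, final.T.ravel()))))
    labels, boundary = two_means_split(final[:, 2])
    return PatterningRun(
        trajectory=traj,
        seed=seed,
        init_noise=init_noise,
        high_set=np.flatnonzero(labels == 1),
        low_set=np.flatnonzero(labels == 0),
        split_boundary=boundary,
        converged=res < residual_tol,
    )


def pattern_time(run: PatterningRun, rate_threshold: float = 1e-4) -> float:
    """End of the patterning transition period.

    Returns the time at which the maximum over cells of |dD/dtau| last
    crosses below ``rate_threshold`` after having exceeded it; 0.0 if the
    threshold is never exceeded (uniform stable run).
    """
    traj = run.trajectory
    params, graph = traj.params, traj.graph
    rates = np.empty(len(traj.t))
    for k in range(len(traj.t)):
        y = traj.y[k].T
        meanD = graph.W @ y[:, 1]
        meanN = graph.W @ y[:, 0]
        dy = rhs_model3(y, params, meanD, meanN)
        rates[k] = np.max(np.abs(dy[:, 1]))
    above = rates > rate_threshold
    if not above.any():
        return 0.0
    last_above = int(np.flatnonzero(above)[-1])
    if last_above + 1 >= len(traj.t):
        return float(traj.t[-1])
    return float(traj.t[last_above + 1])


def _pair_high_R(params: CircuitParams) -> float:
    """NICD level of the high cell in the pair's patterned (asymmetric) state."""
    from .dynamics import pair_fixed_points

    pts = [ss for ss in pair_fixed_points(params) if ss.is_stable]
    if not pts:
        raise ValueError("no stable pair fixed point at these parameters")
    asym = [ss for ss in pts if not np.allclose(ss.state[0], ss.state[1], rtol=1e-4)]
    if not asym:
        raise ValueError("pair is not bistable: no asymmetric stable state")
    return max(float(ss.state[:, 2].max()) for ss in asym)


def match_notch_levels(
    li_params: CircuitParams,
    pfli_params: CircuitParams,
    rel_tol: float = 0.02,
    bracket: tuple[float, float] = (0.05, 40.0),
) -> tuple[CircuitParams, float]:
    """Rescale LI's maximum Notch production to match PFLI's signaling level.

    Bisects a scale factor on ``beta_N`` of the LI circuit so that the NICD
    level of the Notch-high cell in the pair's patterned steady state equals
    the PFLI circuit's within ``rel_tol``.  Returns the adjusted parameters
    and the scale factor (1.0 when the targets already agree).
    """
    target = _pair_high_R(pfli_params)

    def high_R(scale: float) -> Optional[float]:
        try:
            return _pair_high_R(li_params.with_(beta_N=li_params.beta_N * scale))
        except ValueError:
            return None  # pair loses bistability at this scale

    r1 = high_R(1.0)
    if r1 is not None and abs(r1 - target) <= rel_tol * target:
        return li_params, 1.0
    scales = np.geomspace(bracket[0], bracket[1], 33)
    vals = [(float(s), high_R(float(s))) for s in scales]
    vals = [(s, v) for s, v in vals if v is not None]
    pairbr = next(
        (
            (vals[k][0], vals[k + 1][0])
            for k in range(len(vals) - 1)
            if (vals[k][1] - target) * (vals[k + 1][1] - target) <= 0
        ),
        None,
    )
    if pairbr is None:
        best = min((abs(v - target) for _s, v in vals), default=float("inf"))
        raise ValueError(
            f"no beta_N scale in {bracket} matches the target NICD level "
            f"(best gap {best:.3g})"
        )
    scale = optimize.brentq(
        lambda s: high_R(s) - target, pairbr[0], pairbr[1], xtol=1e-5, rtol=1e-5
    )
    adjusted = li_params.with_(beta_N=li_params.beta_N * scale)
    achieved = _pair_high_R(adjusted)
    if abs(achieved - target) > rel_tol * target:
        raise ValueError(
            f"matched NICD level {achieved:.4g} misses target {target:.4g} "
            f"beyond {rel_tol:.0%}"
        )
    return adjusted, float(scale)
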
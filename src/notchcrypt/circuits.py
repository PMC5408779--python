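"""Notch signaling circuit equations.

Three dimensionless model forms of the juxtacrine Notch--Delta circuit are
implemented.  MODEL1 is the dimensional five-species system (Notch mRNA,
NOTCH receptor, Dll mRNA, DLL ligand, cleaved NICD) and is represented only
through its rescaling to MODEL2.  MODEL2 is the dimensionless five-species
system in which the transcriptional regulation strengths are exposed as the
fractions ``S_PF`` (NICD -> Notch positive feedback) and ``S_LI`` (NICD -|
Dll lateral inhibition).  MODEL3 is the three-species protein-only reduction
obtained by a quasi-steady-state elimination of the two mRNAs.

Trans-activation is the bilinear flux ``N_i * <D_j>`` between receptor on
cell *i* and the mean ligand presented by its neighbors; the same flux
depletes the receptor of the receiving cell and (through ``<N_j>``) the
ligand of the sending cells, and it sources the NICD readout ``R``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "ModelForm",
    "ParameterDomainError",
    "CircuitParams",
    "ScalingConstants",
    "CellState",
    "Stimulus",
    "hill_activation",
    "hill_repression",
    "hill_activation_deriv",
    "hill_repression_deriv",
    "rhs_model2",
    "rhs_model3",
    "rhs",
    "jacobian_model3",
    "qssa_reduce",
    "species_names",
]


class ParameterDomainError(ValueError):
    """A parameter lies outside its admissible domain."""


class ModelForm(Enum):
    MODEL1 = 1
    MODEL2 = 2
    MODEL3 = 3


# ---------------------------------------------------------------------------
# Hill regulation functions
# ---------------------------------------------------------------------------

def _check_hill_args(k: float, exponent: float) -> None:
    if k <= 0:
        raise ParameterDomainError(f"saturation coefficient must be > 0, got {k}")
    if exponent < 1:
        raise ParameterDomainError(f"Hill coefficient must be >= 1, got {exponent}")


def hill_activation(x, k: float, p: float):
    """Activating Hill function sigma(x, k, p) = x^p / (k^p + x^p).

    Monotone nondecreasing in ``x``, 0 at ``x = 0`` (for p >= 1), 1/2 at
    ``x = k`` and saturating to 1.  Accepts scalars or arrays.
    """
    _check_hill_args(k, p)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterDomainError("regulator level must be nonnegative")
    with np.errstate(over="ignore"):
        t = (x / k) ** p
        out = np.where(np.isinf(t), 1.0, t / (1.0 + t))
    return out if out.ndim else float(out)


def hill_repression(x, k: float, h: float):
    """Repressing Hill function delta(x, k, h) = k^h / (k^h + x^h).

    Complementary to :func:`hill_activation`: sigma + delta = 1 for equal
    arguments.
    """
    _check_hill_args(k, h)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterDomainError("regulator level must be nonnegative")
    with np.errstate(over="ignore"):
        t = (x / k) ** h
        out = 1.0 / (1.0 + t)
    return out if out.ndim else float(out)


def hill_activation_deriv(x, k: float, p: float):
    """d sigma / dx.  Finite everywhere for p >= 1 (equals 1/k at 0 when p == 1)."""
    _check_hill_args(k, p)
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        u = (x / k) ** p
        out = np.where(
            np.isinf(u), 0.0, (p / k) * (x / k) ** (p - 1.0) / (1.0 + u) ** 2
        )
    out = np.nan_to_num(out, nan=0.0, posinf=0.0)
    return out if out.ndim else float(out)


def hill_repression_deriv(x, k: float, h: float):
    """d delta / dx = -d sigma / dx at equal arguments."""
    return -hill_activation_deriv(x, k, h)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircuitParams:
    """Dimensionless rate constants of one Notch circuit.

    For MODEL2, ``beta_nm``/``beta_dm`` are the maximum Notch/Dll
    transcription rates and ``beta_N``/``beta_D`` the translation rates;
    ``alpha_n``/``alpha_d`` are mRNA decays and ``alpha_N``/``alpha_D``
    protein decays.  For MODEL3 (the protein-only reduction), ``beta_N``/
    ``beta_D`` are the effective maximum production rates, ``alpha_n`` is the
    NOTCH protein decay and ``alpha_D`` the DLL decay; the mRNA fields are
    unused and may be ``None``.

    ``S_PF`` in [0, 1] is the fraction of Notch production under NICD
    positive-feedback control (``S_PF = 0`` gives the pure lateral-inhibition
    circuit); ``S_LI`` the fraction of Dll production under NICD repression.
    The basal/regulated split of the original parameterization is recovered
    as ``beta_n0 = beta_nm (1 - S_PF)``, ``beta_n = beta_nm S_PF`` (and
    likewise for Dll), so ``beta_n0 + beta_n = beta_nm`` holds by
    construction.
    """

    model_form: ModelForm
    beta_N: float
    beta_D: float
    alpha_n: float
    alpha_D: float
    alpha_R: float
    k_p: float
    k_d: float
    p: float
    h: float
    S_PF: float
    S_LI: float
    # MODEL2-only fields
    beta_nm: Optional[float] = None
    beta_dm: Optional[float] = None
    alpha_N: Optional[float] = None
    alpha_d: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("beta_N", "beta_D", "alpha_n", "alpha_D", "alpha_R", "k_p", "k_d"):
            v = getattr(self, name)
            if not v > 0:
                raise ParameterDomainError(f"{name} must be > 0, got {v}")
        for name in ("S_PF", "S_LI"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterDomainError(f"{name} must lie in [0, 1], got {v}")
        for name in ("p", "h"):
            if getattr(self, name) < 1:
                raise ParameterDomainError(f"{name} must be >= 1")
        if self.model_form is ModelForm.MODEL2:
            for name in ("beta_nm", "beta_dm", "alpha_N", "alpha_d"):
                v = getattr(self, name)
                if v is None or not v > 0:
                    raise ParameterDomainError(
                        f"MODEL2 requires {name} > 0, got {v}"
                    )

    # Basal/regulated split of the original (Model 1) parameterization.
    @property
    def beta_n0(self) -> float:
        return self.beta_nm * (1.0 - self.S_PF)

    @property
    def beta_n(self) -> float:
        return self.beta_nm * self.S_PF

    @property
    def beta_d0(self) -> float:
        return self.beta_dm * (1.0 - self.S_LI)

    @property
    def beta_d(self) -> float:
        return self.beta_dm * self.S_LI

    @property
    def n_species(self) -> int:
        return 5 if self.model_form is ModelForm.MODEL2 else 3

    def with_(self, **kw) -> "CircuitParams":
        """Return a copy with the given fields replaced (revalidated)."""
        return replace(self, **kw)

    @classmethod
    def from_basal_rates(
        cls,
        *,
        beta_n0: float,
        beta_n: float,
        beta_d0: float,
        beta_d: float,
        beta_N: float,
        beta_D: float,
        alpha_n: float,
        alpha_N: float,
        alpha_d: float,
        alpha_D: float,
        alpha_R: float,
        k_p: float,
        k_d: float,
        p: float,
        h: float,
    ) -> "CircuitParams":
        """Build MODEL2 parameters from the basal/regulated transcription split.

        ``S_PF = beta_n / (beta_n0 + beta_n)`` and ``S_LI = beta_d /
        (beta_d0 + beta_d)``; the dimensionless Model 1 equations are
        identical to MODEL2 under this substitution.
        """
        beta_nm = beta_n0 + beta_n
        beta_dm = beta_d0 + beta_d
        if beta_nm <= 0 or beta_dm <= 0:
            raise ParameterDomainError("maximum transcription rates must be > 0")
        return cls(
            model_form=ModelForm.MODEL2,
            beta_N=beta_N,
            beta_D=beta_D,
            alpha_n=alpha_n,
            alpha_D=alpha_D,
            alpha_R=alpha_R,
            k_p=k_p,
            k_d=k_d,
            p=p,
            h=h,
            S_PF=beta_n / beta_nm,
            S_LI=beta_d / beta_dm,
            beta_nm=beta_nm,
            beta_dm=beta_dm,
            alpha_N=alpha_N,
            alpha_d=alpha_d,
        )


@dataclass(frozen=True)
class ScalingConstants:
    """Reference scales of the nondimensionalization.

    ``t0`` is the reference timescale, ``k_t`` the dimensional
    trans-activation rate; protein scales satisfy ``N0 = D0 = R0 = t0 k_t``
    so that the dimensionless trans flux is just ``N <D>``.
    """

    t0: float
    k_t: float
    Nm0: float = 1.0
    Dm0: float = 1.0

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.k_t <= 0 or self.Nm0 <= 0 or self.Dm0 <= 0:
            raise ParameterDomainError("scaling constants must be strictly positive")

    @property
    def N0(self) -> float:
        return self.t0 * self.k_t

    D0 = N0
    R0 = N0

    def dimensionless(self, dimensional: dict) -> dict:
        """Map dimensional rate constants to their dimensionless counterparts.

        Keys follow the dimensional model: beta_n0, beta_n, beta_N, beta_d0,
        beta_d, beta_D, alpha_n, alpha_N, alpha_d, alpha_D, alpha_R, k_p, k_d
        (Hill coefficients pass through unchanged).
        """
        t0, N0, Nm0, Dm0 = self.t0, self.N0, self.Nm0, self.Dm0
        d = dimensional
        out = dict(d)
        for key, scale in {
            "beta_n0": t0 / Nm0,
            "beta_n": t0 / Nm0,
            "beta_N": Nm0 * t0 / N0,
            "beta_d0": t0 / Dm0,
            "beta_d": t0 / Dm0,
            "beta_D": Dm0 * t0 / N0,
            "alpha_n": t0,
            "alpha_N": t0,
            "alpha_d": t0,
            "alpha_D": t0,
            "alpha_R": t0,
            "k_p": 1.0 / (self.k_t * N0 * N0),
            "k_d": 1.0 / (self.k_t * N0 * N0),
        }.items():
            if key in d:
                out[key] = d[key] * scale
        return out


@dataclass
class CellState:
    """Per-cell species levels (dimensionless concentrations).

    MODEL3 states carry ``Nm = Dm = None`` (the mRNAs are eliminated).
    """

    N: float
    D: float
    R: float
    Nm: Optional[float] = None
    Dm: Optional[float] = None

    def as_array(self, model_form: ModelForm) -> np.ndarray:
        if model_form is ModelForm.MODEL2:
            if self.Nm is None or self.Dm is None:
                raise ValueError("MODEL2 state requires mRNA levels")
            return np.array([self.Nm, self.N, self.Dm, self.D, self.R])
        return np.array([self.N, self.D, self.R])

    @classmethod
    def from_array(cls, y: np.ndarray, model_form: ModelForm) -> "CellState":
        y = np.asarray(y, dtype=float)
        if model_form is ModelForm.MODEL2:
            return cls(Nm=y[0], N=y[1], Dm=y[2], D=y[3], R=y[4])
        return cls(N=y[0], D=y[1], R=y[2])


@dataclass(frozen=True)
class Stimulus:
    """External ligand/receptor presented to cells (single-cell protocol).

    ``D_ext`` adds to every cell's neighbor-mean ligand ``<D_j>``; ``N_ext``
    (0 in the standard protocol) adds to ``<N_j>``.
    """

    D_ext: float = 0.0
    N_ext: float = 0.0

    def __post_init__(self) -> None:
        if self.D_ext < 0 or self.N_ext < 0:
            raise ParameterDomainError("external levels must be nonnegative")


def species_names(model_form: ModelForm) -> tuple[str, ...]:
    if model_form is ModelForm.MODEL2:
        return ("Nm", "N", "Dm", "D", "R")
    return ("N", "D", "R")


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def _check_state(y: np.ndarray, n_species: int) -> np.ndarray:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[1] != n_species:
        raise ValueError(f"state must have {n_species} species, got shape {y.shape}")
    if np.any(y < 0):
        raise ValueError("negative state components are outside the model domain")
    return y


def rhs_model2(y, params: CircuitParams, meanD, meanN):
    """Time-derivatives of the five-species dimensionless circuit.

    ``y`` has columns (Nm, N, Dm, D, R) and one row per cell; ``meanD`` /
    ``meanN`` are the per-cell neighbor means (plus any external stimulus).
    """
    if params.model_form is not ModelForm.MODEL2:
        raise ValueError("rhs_model2 requires MODEL2 parameters")
    y = _check_state(y, 5)
    meanD = np.broadcast_to(np.asarray(meanD, dtype=float), y.shape[0])
    meanN = np.broadcast_to(np.asarray(meanN, dtype=float), y.shape[0])
    Nm, N, Dm, D, R = y.T
    s = N * meanD  # trans-activation flux
    act = (1.0 - params.S_PF) + params.S_PF * hill_activation(s, params.k_p, params.p)
    rep = (1.0 - params.S_LI) + params.S_LI * hill_repression(s, params.k_d, params.h)
    dNm = params.beta_nm * act - params.alpha_n * Nm
    dN = params.beta_N * Nm - params.alpha_N * N - s
    dDm = params.beta_dm * rep - params.alpha_d * Dm
    dD = params.beta_D * Dm - params.alpha_D * D - meanN * D
    dR = s - params.alpha_R * R
    return np.column_stack([dNm, dN, dDm, dD, dR])


def rhs_model3(y, params: CircuitParams, meanD, meanN):
    """Time-derivatives of the protein-only circuit (columns N, D, R)."""
    if params.model_form is not ModelForm.MODEL3:
        raise ValueError("rhs_model3 requires MODEL3 parameters")
    y = _check_state(y, 3)
    meanD = np.broadcast_to(np.asarray(meanD, dtype=float), y.shape[0])
    meanN = np.broadcast_to(np.asarray(meanN, dtype=float), y.shape[0])
    N, D, R = y.T
    s = N * meanD
    act = (1.0 - params.S_PF) + params.S_PF * hill_activation(s, params.k_p, params.p)
    rep = (1.0 - params.S_LI) + params.S_LI * hill_repression(s, params.k_d, params.h)
    dN = params.beta_N * act - params.alpha_n * N - s
    dD = params.beta_D * rep - params.alpha_D * D - meanN * D
    dR = s - params.alpha_R * R
    return np.column_stack([dN, dD, dR])


def rhs(y, params: CircuitParams, meanD, meanN):
    """Dispatch to the model form of ``params``."""
    if params.model_form is ModelForm.MODEL3:
        return rhs_model3(y, params, meanD, meanN)
    if params.model_form is ModelForm.MODEL2:
        return rhs_model2(y, params, meanD, meanN)
    raise ValueError("MODEL1 is integrated via its MODEL2 rescaling")


def jacobian_model3(
    y: np.ndarray,
    params: CircuitParams,
    W: np.ndarray,
    stimulus: Stimulus | None = None,
) -> np.ndarray:
    """Analytic Jacobian of the MODEL3 multicell system.

    State ordering is species-major: (N_1..N_n, D_1..D_n, R_1..R_n).  ``W``
    is the row-normalized neighbor-weight matrix defining the means
    ``<X_j>_i = sum_k W[i, k] X_k``.
    """
    y = _check_state(y, 3)
    n = y.shape[0]
    W = np.asarray(W, dtype=float)
    N, D, _ = y.T
    d_ext = stimulus.D_ext if stimulus else 0.0
    n_ext = stimulus.N_ext if stimulus else 0.0
    meanD = W @ D + d_ext
    meanN = W @ N + n_ext
    s = N * meanD
    a = params.beta_N * params.S_PF * hill_activation_deriv(s, params.k_p, params.p) - 1.0
    g = params.beta_D * params.S_LI * hill_repression_deriv(s, params.k_d, params.h)
    J = np.zeros((3 * n, 3 * n))
    sN = slice(0, n)
    sD = slice(n, 2 * n)
    sR = slice(2 * n, 3 * n)
    idx = np.arange(n)
    JNN = np.zeros((n, n))
    JNN[idx, idx] = a * meanD - params.alpha_n
    JND = (a * N)[:, None] * W
    JDN = -np.diag(D) @ W
    JDN[idx, idx] += g * meanD
    JDD = (g * N)[:, None] * W
    JDD[idx, idx] += -(params.alpha_D + meanN)
    JRN = np.diag(meanD)
    JRD = N[:, None] * W
    JRR = -params.alpha_R * np.eye(n)
    J[sN, sN] = JNN
    J[sN, sD] = JND
    J[sD, sN] = JDN
    J[sD, sD] = JDD
    J[sR, sN] = JRN
    J[sR, sD] = JRD
    J[sR, sR] = JRR
    return J


# ---------------------------------------------------------------------------
# Quasi-steady-state reduction
# ---------------------------------------------------------------------------

def qssa_reduce(params: CircuitParams) -> CircuitParams:
    """Reduce a MODEL2 parameter set to MODEL3 by eliminating the mRNAs.

    Setting the mRNA derivatives to zero gives ``Nm* = (beta_nm/alpha_n)
    [(1-S_PF) + S_PF sigma]`` (and the Dll analogue); substituting into the
    protein equations yields the MODEL3 effective production rates
    ``beta_N' = beta_N beta_nm / alpha_n`` and ``beta_D' = beta_D beta_dm /
    alpha_d``.  The reduced NOTCH decay is MODEL2's protein decay
    ``alpha_N``.
    """
    if params.model_form is not ModelForm.MODEL2:
        raise ValueError("qssa_reduce expects MODEL2 parameters")
    if not (params.alpha_n > 0 and params.alpha_d > 0):
        raise ParameterDomainError("mRNA degradation rates must be > 0")
    return CircuitParams(
        model_form=ModelForm.MODEL3,
        beta_N=params.beta_N * params.beta_nm / params.alpha_n,
        beta_D=params.beta_D * params.beta_dm / params.alpha_d,
        alpha_n=params.alpha_N,
        alpha_D=params.alpha_D,
        alpha_R=params.alpha_R,
        k_p=params.k_p,
        k_d=params.k_d,
        p=params.p,
        h=params.h,
        S_PF=params.S_PF,
        S_LI=params.S_LI,
    )
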
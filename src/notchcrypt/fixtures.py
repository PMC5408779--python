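"""Named reference parameter sets.

The circuit literature fixes the qualitative regimes (lateral inhibition
patterns only with sufficiently cooperative ligand repression; adding the
Notch positive feedback patterns already at low cooperativity) but no
canonical numeric values exist for this system, so these presets are
fixtures of this package, chosen once so that:

* ``li_default`` (pure LI, ``S_PF = 0``) is pair-bistable at ``h = 2`` but
  not at ``h = 1`` and responds monostably to external ligand;
* ``pfli_default`` (LI + Notch positive feedback) is pair-bistable already
  at ``h = 1, p = 2`` and shows single-cell hysteresis in external ligand.

All rates are dimensionless (time in units of the reference timescale,
concentrations in units of the trans-activation scale ``t0 * k_t``).
"""

from __future__ import annotations

from .circuits import CircuitParams, ModelForm

__all__ = [
    "pfli_default",
    "li_default",
    "model2_default",
    "crypt_circuits",
    "named_circuits",
]

#: Strength of the NICD -> Notch positive feedback in the PFLI preset.
DEFAULT_S_PF = 0.95


def pfli_default() -> CircuitParams:
    """LI plus Notch positive feedback (protein-only MODEL3 form).

    Ligand cooperativity defaults to ``h = 3``, the smallest integer at
    which pure LI destabilizes the homogeneous state on a 6-neighbor
    (hexagonally packed) lattice, so that both circuits pattern in the
    deterministic multicell analyses.
    """
    return CircuitParams(
        model_form=ModelForm.MODEL3,
        beta_N=4.0,
        beta_D=12.0,
        alpha_n=1.0,
        alpha_D=1.0,
        alpha_R=1.0,
        k_p=1.25,
        k_d=0.5,
        p=2.0,
        h=3.0,
        S_PF=DEFAULT_S_PF,
        S_LI=1.0,
    )


def crypt_circuits() -> dict[str, CircuitParams]:
    """Circuit presets for the stochastic crypt experiments.

    The crypt probes robustness at low ligand cooperativity (``h = 2``),
    the regime where lateral inhibition is marginally patterning-competent
    on the cell-contact graph and the positive feedback's contribution is
    decisive; both circuits are pair-bistable there, so both form mosaics
    in a slowly proliferating niche.
    """
    pf = pfli_default().with_(h=2.0)
    return {"li": pf.with_(S_PF=0.0), "pfli": pf}


def li_default() -> CircuitParams:
    """Pure lateral inhibition: the PFLI preset with the feedback removed."""
    return pfli_default().with_(S_PF=0.0)


def model2_default(mrna_rate_scale: float = 10.0) -> CircuitParams:
    """Five-species MODEL2 set whose QSSA reduction equals ``pfli_default``.

    mRNA turnover is ``mrna_rate_scale`` times faster than protein turnover;
    transcription rates are chosen so that ``beta_N * beta_nm / alpha_n``
    and ``beta_D * beta_dm / alpha_d`` reproduce the MODEL3 production
    rates.
    """
    m3 = pfli_default()
    alpha_m = mrna_rate_scale  # protein decays are 1 in the default set
    return CircuitParams(
        model_form=ModelForm.MODEL2,
        beta_N=m3.beta_N,
        beta_D=m3.beta_D,
        alpha_n=alpha_m,
        alpha_D=m3.alpha_D,
        alpha_R=m3.alpha_R,
        k_p=m3.k_p,
        k_d=m3.k_d,
        p=m3.p,
        h=m3.h,
        S_PF=m3.S_PF,
        S_LI=m3.S_LI,
        beta_nm=alpha_m,
        beta_dm=alpha_m,
        alpha_N=1.0,
        alpha_d=alpha_m,
    )


def named_circuits() -> dict[str, CircuitParams]:
    return {
        "li_default": li_default(),
        "pfli_default": pfli_default(),
        "model2_default": model2_default(),
    }
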
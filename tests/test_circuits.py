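"""Unit tests for the circuit equations and their reductions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notchcrypt.circuits import (
    CellState,
    CircuitParams,
    ModelForm,
    ParameterDomainError,
    ScalingConstants,
    hill_activation,
    hill_activation_deriv,
    hill_repression,
    jacobian_model3,
    qssa_reduce,
    rhs_model2,
    rhs_model3,
)
from notchcrypt.integrate import integrate
from notchcrypt.lattice import NeighborGraph

from conftest import random_model3_params


@pytest.mark.parametrize(
    "func,x,k,exp,expected",
    [
        (hill_activation, 1.7, 1.7, 3.0, 0.5),
        (hill_activation, 0.0, 1.0, 2.0, 0.0),
        (hill_activation, 2.0, 1.0, 4.0, 16.0 / 17.0),
        (hill_repression, 0.0, 2.3, 4.0, 1.0),
        (hill_repression, 0.4, 0.4, 1.0, 0.5),
        (hill_repression, 3.0, 1.0, 2.0, 0.1),
    ],
)
def test_hill_function_values(func, x, k, exp, expected):
    assert func(x, k, exp) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [dict(k=0.0, p=2.0), dict(k=-1.0, p=2.0), dict(k=1.0, p=0.5)])
def test_hill_functions_reject_bad_parameters(bad):
    with pytest.raises(ParameterDomainError):
        hill_activation(1.0, bad["k"], bad["p"])
    with pytest.raises(ParameterDomainError):
        hill_repression(1.0, bad["k"], bad["p"])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    x=st.floats(0.0, 1e6),
    k=st.floats(1e-3, 1e3),
    n=st.floats(1.0, 8.0),
)
def test_activation_and_repression_are_complementary(x, k, n):
    """sigma + delta = 1 for identical arguments, over a broad random grid."""
    assert hill_activation(x, k, n) + hill_repression(x, k, n) == pytest.approx(1.0, abs=1e-12)


def test_hill_activation_monotone_and_saturating():
    x = np.linspace(0.0, 50.0, 400)
    y = hill_activation(x, 1.3, 2.5)
    assert np.all(np.diff(y) >= 0)
    assert y[-1] > 0.999


class TestCircuitParams:
    def test_basal_regulated_split_is_consistent(self, model2_params):
        p = model2_params
        assert p.beta_n0 + p.beta_n == pytest.approx(p.beta_nm)
        assert p.beta_d0 + p.beta_d == pytest.approx(p.beta_dm)
        assert p.beta_n / p.beta_nm == pytest.approx(p.S_PF)

    def test_from_basal_rates_recovers_strengths(self):
        p = CircuitParams.from_basal_rates(
            beta_n0=1.0, beta_n=3.0, beta_d0=0.0, beta_d=5.0,
            beta_N=2.0, beta_D=2.0, alpha_n=1.0, alpha_N=1.0,
            alpha_d=1.0, alpha_D=1.0, alpha_R=1.0,
            k_p=1.0, k_d=1.0, p=2.0, h=2.0,
        )
        assert p.S_PF == pytest.approx(0.75)
        assert p.S_LI == pytest.approx(1.0)
        assert p.beta_nm == pytest.approx(4.0)

    @pytest.mark.parametrize("field,value", [("S_PF", 1.5), ("S_PF", -0.1), ("beta_N", 0.0), ("h", 0.5)])
    def test_domain_violations_rejected(self, pfli_params, field, value):
        with pytest.raises(ParameterDomainError):
            pfli_params.with_(**{field: value})

    def test_scaling_constants_rescale_rates(self):
        sc = ScalingConstants(t0=2.0, k_t=0.5)
        assert sc.N0 == pytest.approx(1.0)
        out = sc.dimensionless({"alpha_n": 0.7, "beta_n0": 1.1, "h": 2.0})
        assert out["alpha_n"] == pytest.approx(1.4)  # alpha * t0
        assert out["h"] == 2.0


class TestRhs:
    def test_basal_synthesis_only_at_origin(self, model2_params):
        """With no feedback input, only the basal transcription terms fire."""
        p = model2_params.with_(S_PF=0.0)
        dy = rhs_model2(np.zeros((1, 5)), p, meanD=0.0, meanN=0.0)[0]
        assert dy[0] == pytest.approx(p.beta_nm)  # dNm
        assert dy[2] == pytest.approx(p.beta_dm)  # dDm
        assert dy[[1, 3, 4]] == pytest.approx([0.0, 0.0, 0.0])

    def test_nicd_fixed_point_relation(self, pfli_params):
        """At any fixed point of R: R* = N <D> / alpha_R."""
        y = np.array([[1.3, 0.7, 1.3 * 2.0 / pfli_params.alpha_R]])
        dy = rhs_model3(y, pfli_params, meanD=2.0, meanN=0.0)[0]
        assert dy[2] == pytest.approx(0.0, abs=1e-12)

    def test_model3_numeric_spot_check(self, pfli_params):
        """Term-by-term independent evaluation of the printed equations."""
        p = pfli_params
        N, D, R, mD, mN = 0.8, 2.5, 0.3, 1.2, 0.4
        s = N * mD
        sig = (s / p.k_p) ** p.p / (1 + (s / p.k_p) ** p.p)
        dlt = 1.0 / (1 + (s / p.k_d) ** p.h)
        expected = np.array(
            [
                p.beta_N * ((1 - p.S_PF) + p.S_PF * sig) - p.alpha_n * N - s,
                p.beta_D * ((1 - p.S_LI) + p.S_LI * dlt) - p.alpha_D * D - mN * D,
                s - p.alpha_R * R,
            ]
        )
        got = rhs_model3(np.array([[N, D, R]]), p, mD, mN)[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_model2_numeric_spot_check(self, model2_params):
        p = model2_params
        y = np.array([[0.5, 0.8, 1.1, 2.5, 0.3]])
        mD, mN = 1.2, 0.4
        s = 0.8 * mD
        sig = (s / p.k_p) ** p.p / (1 + (s / p.k_p) ** p.p)
        dlt = 1.0 / (1 + (s / p.k_d) ** p.h)
        expected = np.array(
            [
                p.beta_nm * ((1 - p.S_PF) + p.S_PF * sig) - p.alpha_n * 0.5,
                p.beta_N * 0.5 - p.alpha_N * 0.8 - s,
                p.beta_dm * ((1 - p.S_LI) + p.S_LI * dlt) - p.alpha_d * 1.1,
                p.beta_D * 1.1 - p.alpha_D * 2.5 - mN * 2.5,
                s - p.alpha_R * 0.3,
            ]
        )
        assert rhs_model2(y, p, mD, mN)[0] == pytest.approx(expected, rel=1e-12)

    def test_pure_li_decay_limit(self, li_params):
        """S_PF = 0 and no external ligand: NOTCH relaxes linearly to beta_N/alpha_n."""
        y = np.array([[2.0, 1.0, 0.5]])
        dy = rhs_model3(y, li_params, meanD=0.0, meanN=0.0)[0]
        assert dy[0] == pytest.approx(li_params.beta_N - li_params.alpha_n * 2.0)

    def test_full_repression_limit(self, pfli_params):
        """Saturated NICD shuts ligand production down to pure decay."""
        p = pfli_params.with_(S_LI=1.0)
        y = np.array([[50.0, 3.0, 0.0]])
        dy = rhs_model3(y, p, meanD=50.0, meanN=0.0)[0]
        assert dy[1] == pytest.approx(-p.alpha_D * 3.0, rel=1e-4)

    def test_negative_state_rejected(self, pfli_params):
        with pytest.raises(ValueError):
            rhs_model3(np.array([[-0.1, 1.0, 0.0]]), pfli_params, 0.0, 0.0)

    def test_spf_zero_matches_independent_li_rhs(self, li_params):
        """The PFLI equations with S_PF = 0 equal an independently coded LI model."""
        rng = np.random.default_rng(7)
        y = rng.uniform(0.0, 3.0, size=(5, 3))
        mD = rng.uniform(0.0, 3.0, size=5)
        mN = rng.uniform(0.0, 3.0, size=5)

        def li_rhs(y, p, mD, mN):  # independent implementation
            out = np.empty_like(y)
            for i in range(len(y)):
                N, D, R = y[i]
                s = N * mD[i]
                delta = p.k_d**p.h / (p.k_d**p.h + s**p.h)
                out[i, 0] = p.beta_N - p.alpha_n * N - s
                out[i, 1] = p.beta_D * delta - p.alpha_D * D - mN[i] * D
                out[i, 2] = s - p.alpha_R * R
            return out

        assert rhs_model3(y, li_params, mD, mN) == pytest.approx(li_rhs(y, li_params, mD, mN))


class TestJacobian:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_matches_finite_difference(self, seed, pair_graph):
        rng = np.random.default_rng(seed)
        params = random_model3_params(rng)
        y = rng.uniform(0.1, 3.0, size=(2, 3))
        J = jacobian_model3(y, params, pair_graph.W)
        eps = 1e-7
        flat = y.T.ravel()

        def f(v):
            yy = v.reshape(3, 2).T
            mD = pair_graph.W @ yy[:, 1]
            mN = pair_graph.W @ yy[:, 0]
            return rhs_model3(yy, params, mD, mN).T.ravel()

        J_fd = np.empty_like(J)
        for j in range(6):
            e = np.zeros(6)
            e[j] = eps
            J_fd[:, j] = (f(flat + e) - f(flat - e)) / (2 * eps)
        assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-6)


class TestQssaReduction:
    def test_printed_substitution(self):
        p = CircuitParams(
            model_form=ModelForm.MODEL2, beta_N=1.0, beta_D=1.0,
            alpha_n=2.0, alpha_D=1.0, alpha_R=1.0, k_p=1.0, k_d=1.0,
            p=2.0, h=2.0, S_PF=0.5, S_LI=1.0,
            beta_nm=2.0, beta_dm=3.0, alpha_N=1.0, alpha_d=3.0,
        )
        r = qssa_reduce(p)
        assert r.model_form is ModelForm.MODEL3
        assert r.beta_N == pytest.approx(1.0)  # beta_N * beta_nm / alpha_n
        assert r.beta_D == pytest.approx(1.0)  # beta_D * beta_dm / alpha_d
        assert r.alpha_n == pytest.approx(p.alpha_N)

    def test_identity_when_rates_cancel(self, model2_params):
        p = model2_params.with_(beta_nm=model2_params.alpha_n, beta_dm=model2_params.alpha_d)
        r = qssa_reduce(p)
        assert r.beta_N == pytest.approx(p.beta_N)
        assert r.beta_D == pytest.approx(p.beta_D)

    def test_requires_model2(self, pfli_params):
        with pytest.raises(ValueError):
            qssa_reduce(pfli_params)

    @pytest.mark.parametrize("scale,tol", [(10.0, 0.15), (100.0, 0.02)])
    def test_trajectories_converge_with_fast_mrna(self, pfli_params, pair_graph, scale, tol):
        """MODEL2 pair trajectories approach the reduced MODEL3 trajectories
        as mRNA turnover outpaces protein turnover, with shrinking error."""
        from notchcrypt.fixtures import model2_default

        m2 = model2_default(mrna_rate_scale=scale)
        m3 = qssa_reduce(m2)
        y3 = np.array([[0.5, 1.0, 0.0], [0.6, 0.8, 0.0]])
        nm0 = m2.beta_nm / m2.alpha_n  # mRNA quasi-steady levels at zero signal
        dm0 = m2.beta_dm / m2.alpha_d
        y2 = np.column_stack([np.full(2, nm0 * 0), y3[:, 0], np.full(2, dm0 * 0), y3[:, 1], y3[:, 2]])
        t_eval = np.linspace(0.0, 30.0, 61)
        tr2 = integrate(m2, y2, pair_graph, 30.0, t_eval=t_eval)
        tr3 = integrate(m3, y3, pair_graph, 30.0, t_eval=t_eval)
        protein2 = tr2.y[:, [1, 3, 4], :]
        err = np.max(np.abs(protein2 - tr3.y)) / np.max(np.abs(tr3.y))
        assert err < tol


class TestCellState:
    def test_roundtrip_both_forms(self):
        s = CellState(N=1.0, D=2.0, R=3.0, Nm=0.1, Dm=0.2)
        assert CellState.from_array(s.as_array(ModelForm.MODEL2), ModelForm.MODEL2) == s
        s3 = CellState(N=1.0, D=2.0, R=3.0)
        arr = s3.as_array(ModelForm.MODEL3)
        assert arr.tolist() == [1.0, 2.0, 3.0]

    def test_model2_array_requires_mrna(self):
        with pytest.raises(ValueError):
            CellState(N=1.0, D=2.0, R=3.0).as_array(ModelForm.MODEL2)


@pytest.mark.parametrize("seed", range(4))
def test_nonnegativity_preserved_under_integration(seed, pair_graph):
    """Species stay nonnegative (within solver tolerance) from random
    nonnegative initial conditions and random parameters."""
    rng = np.random.default_rng(100 + seed)
    params = random_model3_params(rng)
    y0 = rng.uniform(0.0, 5.0, size=(2, 3))
    traj = integrate(params, y0, pair_graph, 50.0)
    assert traj.y.min() >= 0.0  # clamped; larger violations raise
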
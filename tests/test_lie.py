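import numpy as np
import pytest
import sympy as sp

import odeident as oi
from odeident.lie import (build_jacobi, emit_dependency_pde, generating_series,
                          iter_words, lie_derivative, null_space_basis,
                          symbolic_rank, verify_candidates)


def test_first_lie_derivative_is_output_derivative(models):
    m = models["m1"]
    x1, x2 = m.states
    p1, p2, p3 = m.params
    got = lie_derivative(m.outputs[0], m.drift, m.states)
    assert sp.expand(got - (p1 * x1**2 + p2 * x1 * x2)) == 0


def test_lie_derivative_of_constant_is_zero(models):
    m = models["m1"]
    assert lie_derivative(sp.Integer(5), m.drift, m.states) == 0


def test_toy_second_lie_derivative_hand_oracle(models):
    # d/dt of (1 + theta x^2) along the flow: 2 theta x (1 + theta x^2)
    m = models["toy_eq48"]
    x1, th1 = m.states[0], m.params[0]
    L1 = lie_derivative(m.outputs[0], m.drift, m.states)
    L2 = lie_derivative(L1, m.drift, m.states)
    assert sp.expand(L2 - 2 * th1 * x1 * (1 + th1 * x1**2)) == 0


def test_word_ordering():
    assert list(iter_words(0, 3)) == [(), (0,), (0, 0), (0, 0, 0)]
    words = list(iter_words(1, 2))
    assert words == [(), (0,), (1,), (0, 0), (0, 1), (1, 0), (1, 1)]


def test_uncontrolled_series_counts(models):
    ser = generating_series(models["m3_epo"], 3)
    # (max_order + 1) words, two outputs each
    assert len(ser.entries) == 4 * 2
    assert not ser.controlled


def test_zero_output_series_is_zero(models):
    import dataclasses
    m = dataclasses.replace(models["m1"], outputs=(sp.S.Zero,))
    ser = generating_series(m, 3)
    assert all(e == 0 for e in ser.coefficients())


def test_m2_fliess_coefficients(models):
    """The input-model series contains the known coefficient set
    {x1(0), -p2 x1(0) - p3 x2(0), p0 p2, -p0 p2^2 + p0 p3 (p3 x2(0) - p1)}
    (up to overall row sign, which does not affect rank or null-space)."""
    m = models["m2"]
    x1, x2 = m.states
    p0, p1, p2, p3 = m.params
    x10, x20 = sp.symbols("x10 x20")
    ser = generating_series(m, 3)
    at0 = [sp.expand(e.xreplace({x1: x10, x2: x20})) for e in ser.coefficients()]
    expected = [x10, -p2 * x10 - p3 * x20, p0 * p2,
                -p0 * p2**2 + p0 * p3 * (p3 * x20 - p1)]
    for want in expected:
        assert any(sp.expand(c - want) == 0 or sp.expand(c + want) == 0
                   for c in at0), f"coefficient {want} not found"


class TestJacobiMatrix:
    def test_m1_restricted_matrix_and_null_space(self, models):
        """x2(0) = 0, x1(0) normalised to 1: the 4x2 matrix restricted to
        {p2, p3} has rows (0,0), (0,0), (p3, p2), ((1+6 p1) p3, (1+6 p1) p2)
        and null-space basis {-p2/p3, 1}."""
        m = models["m1"]
        x1, x2 = m.states
        p1, p2, p3 = m.params
        J = build_jacobi(generating_series(m, 3), (p2, p3), {x1: 1, x2: 0})
        expected = sp.Matrix([[0, 0], [0, 0], [p3, p2],
                              [(1 + 6 * p1) * p3, (1 + 6 * p1) * p2]])
        assert sp.simplify(J.M - expected) == sp.zeros(4, 2)
        assert symbolic_rank(J) == 1
        basis = null_space_basis(J)
        assert len(basis) == 1
        vec = basis.vectors[0]
        assert sp.simplify(vec[0] + p2 / p3) == 0 and vec[1] == 1

    def test_m1_rank_two_with_nonzero_x2_initial_value(self, models):
        m = models["m1"]
        x1, x2 = m.states
        _, p2, p3 = m.params
        x10, x20 = sp.symbols("x10 x20")
        J = build_jacobi(generating_series(m, 3), (p2, p3), {x1: x10, x2: x20})
        assert symbolic_rank(J) == 2
        assert len(null_space_basis(J)) == 0

    def test_m2_last_column_zero_and_null_space(self, models):
        m = models["m2"]
        x1, x2 = m.states
        p0, p1, p2, p3 = m.params
        J = build_jacobi(generating_series(m, 3), m.params,
                         {x1: sp.Symbol("x10"), x2: p1 / p3})
        assert all(sp.simplify(e) == 0 for e in J.M[:, 3])
        basis = null_space_basis(J)
        assert len(basis) == 1
        assert tuple(basis.vectors[0]) == (0, 0, 0, 1)

    def test_m2_rank_four_with_p2_over_p3(self, models):
        m = models["m2"]
        x1, x2 = m.states
        p0, p1, p2, p3 = m.params
        J = build_jacobi(generating_series(m, 4), m.params,
                         {x1: sp.Symbol("x10"), x2: p2 / p3})
        assert symbolic_rank(J) == 4

    def test_absent_parameter_gives_zero_column(self, models):
        m = models["m1"]
        x1, x2 = m.states
        extra = sp.Symbol("q_absent")
        J = build_jacobi(generating_series(m, 3), (m.params[0], extra),
                         {x1: 1, x2: 0})
        assert all(e == 0 for e in J.M[:, 1])

    def test_zero_matrix_has_rank_zero(self):
        assert symbolic_rank(sp.zeros(3, 2)) == 0

    def test_full_rank_square_matrix_has_empty_basis(self):
        from odeident.lie import JacobiMatrix
        a, b = sp.symbols("a b")
        J = JacobiMatrix(M=sp.Matrix([[a, 0], [0, b]]), selected=(a, b), rows=())
        assert len(null_space_basis(J)) == 0

    def test_restriction_consistency(self, models):
        """Columns of the full Jacobi matrix equal the directly built
        restricted matrix for the same unknown subset."""
        m = models["m2"]
        x1, x2 = m.states
        p0, p1, p2, p3 = m.params
        subs = {x1: sp.Symbol("x10"), x2: p1 / p3}
        ser = generating_series(m, 3)
        full = build_jacobi(ser, m.params, subs)
        restricted = build_jacobi(ser, (p1, p3), subs)
        assert sp.simplify(full.M[:, [1, 3]] - restricted.M) == sp.zeros(
            *restricted.M.shape)


def test_random_rational_point_rank_oracle(models):
    """Numeric rank at seeded random rational points equals the generic
    symbolic rank (probabilistic cross-oracle)."""
    m = models["m1"]
    x1, x2 = m.states
    _, p2, p3 = m.params
    x10, x20 = sp.symbols("x10 x20")
    for subs, _label in [({x1: x10, x2: 0}, "restricted"),
                         ({x1: x10, x2: x20}, "generic")]:
        J = build_jacobi(generating_series(m, 3), (p2, p3), subs)
        expected = symbolic_rank(J)
        rng = np.random.default_rng(42)
        for _ in range(5):
            point = {s: sp.Rational(int(rng.integers(1, 50)),
                                    int(rng.integers(1, 50)))
                     for s in J.M.free_symbols}
            num = np.array(J.M.xreplace(point), dtype=float)
            sv = np.linalg.svd(num, compute_uv=False)
            numeric_rank = int(np.sum(sv > 1e-9 * max(sv[0], 1)))
            assert numeric_rank == expected


class TestDependencyPde:
    def test_m1_pde_and_candidate_verification(self, models):
        """The null vector {-p2/p3, 1} encodes the PDE
        -(p2/p3) dphi/dp2 + dphi/dp3 = 0, solved by phi = p2 p3."""
        m = models["m1"]
        x1, x2 = m.states
        _, p2, p3 = m.params
        J = build_jacobi(generating_series(m, 3), (p2, p3), {x1: 1, x2: 0})
        vec = null_space_basis(J).vectors[0]
        pde = emit_dependency_pde(vec, (p2, p3))
        assert pde.residual(p2 * p3) == 0
        assert pde.residual(p2 + p3) != 0
        assert "d(phi)/d(p2)" in str(pde) and "d(phi)/d(p3)" in str(pde)

    def test_unit_vector_pde_is_single_derivative(self):
        a, b = sp.symbols("a b")
        pde = emit_dependency_pde((0, 1), (a, b))
        assert str(pde) == "(1)*d(phi)/d(b) = 0"
        assert pde.residual(a) == 0 and pde.residual(b) != 0


class TestStagedVerification:
    def test_toy_candidate_is_identifiable(self, models):
        m = models["toy_eq48"]
        res = verify_candidates(m, m.params, {m.states[0]: 0})
        assert res.verdict == "identifiable"
        assert res.unidentifiable_set == ()

    def test_m2_p3_stays_unidentifiable(self, models):
        m = models["m2"]
        x1, x2 = m.states
        p3 = m.params[3]
        res = verify_candidates(m, (p3,), {x1: sp.Symbol("x10"),
                                           x2: m.params[1] / p3})
        assert res.verdict == "unidentifiable"
        assert res.unidentifiable_set == ("p3",)
        assert [tuple(v) for v in res.basis.vectors] == [(1,)]

    def test_basis_vectors_annihilate_the_matrix(self, models):
        m = models["m1"]
        x1, x2 = m.states
        _, p2, p3 = m.params
        J = build_jacobi(generating_series(m, 4), (p2, p3), {x1: 1, x2: 0})
        for vec in null_space_basis(J).vectors:
            prod = J.M * sp.Matrix(2, 1, list(vec))
            assert sp.simplify(prod) == sp.zeros(J.M.rows, 1)

    def test_empty_selection_rejected(self, models):
        with pytest.raises(ValueError, match="nonempty"):
            verify_candidates(models["m1"], (), {})
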
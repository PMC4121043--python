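"""Unit and property tests for the generic homotopy-decomposition engine."""
import random

import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from hdmks import engine
from hdmks._symbols import p as P, t, x
from hdmks.engine import (
    AmbiguityError,
    GeneralProblem,
    HePolynomial,
    IntegrationFailure,
    ProductFormNonlinearity,
    SeriesTerm,
    abel_inverse,
    hdm_solve,
    he_polynomials_bruteforce,
    he_polynomials_convolution,
    initial_guess,
    symbolic_equal,
)

M_, A_ = sp.symbols("m a", positive=True)


def _zero(e):
    return sp.simplify(sp.expand(e)) == 0


# --------------------------------------------------------------------------
# initial guess
# --------------------------------------------------------------------------

@pytest.mark.parametrize("time_order,data,expected", [
    (1, [M_ * sp.exp(-(x**2))], M_ * sp.exp(-(x**2))),
    (2, [x, 2 * x], x + 2 * x * t),      # explicit first-derivative data
    (2, [x], x),                          # omitted top coefficient defaults to 0
    (1, [sp.Integer(0)], sp.Integer(0)),
    (3, [sp.sin(x), x], sp.sin(x) + x * t),
])
def test_initial_guess_taylor_polynomial(time_order, data, expected):
    prob = GeneralProblem.single(data, time_order=time_order)
    assert _zero(initial_guess(prob)["U"] - expected)


def test_missing_initial_data_is_a_specification_error():
    with pytest.raises(ValueError, match="initial"):
        GeneralProblem.single([], time_order=1)
    with pytest.raises(ValueError, match="rho"):
        GeneralProblem(
            fields=("u", "rho"), initial_data={"u": [x]},
            linear_op=lambda F: {k: 0 for k in F},
        )


# --------------------------------------------------------------------------
# Abel-kernel inverse time operator
# --------------------------------------------------------------------------

@pytest.mark.parametrize("integrand,m,expected", [
    (sp.Symbol("c0"), 1, sp.Symbol("c0") * t),
    (sp.Integer(1), 2, t**2 / 2),
    (t, 1, t**2 / 2),
    (A_ * sp.diff(M_ * sp.exp(-(x**2)), x, 2), 1,
     2 * A_ * sp.exp(-(x**2)) * M_ * t * (-1 + 2 * x**2)),
])
def test_abel_inverse_closed_forms(integrand, m, expected):
    assert _zero(abel_inverse(integrand, m) - expected)


def test_abel_inverse_rejects_nonintegrable():
    with pytest.raises(IntegrationFailure):
        abel_inverse(sp.exp(sp.tan(t)) * sp.exp(-x), 1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(coeffs=st.lists(st.integers(-4, 4), min_size=1, max_size=4),
       m=st.integers(1, 3))
def test_abel_inverse_vanishes_at_t0(coeffs, m):
    """The m-fold time integral of any t-polynomial vanishes at t = 0."""
    integrand = sum(c * t**k for k, c in enumerate(coeffs)) * sp.exp(-x)
    result = abel_inverse(integrand, m)
    assert result.subs(t, 0) == 0


# --------------------------------------------------------------------------
# He polynomials
# --------------------------------------------------------------------------

def _terms(*exprs):
    return [SeriesTerm(i, {"U": e}) for i, e in enumerate(exprs)]


def test_he_bruteforce_square():
    U0, U1 = sp.Function("U0")(x), sp.Function("U1")(x)
    terms = _terms(U0, U1)
    sq = lambda F: F["U"] ** 2
    assert _zero(he_polynomials_bruteforce(sq, terms, 0).expression - U0**2)
    assert _zero(he_polynomials_bruteforce(sq, terms, 1).expression - 2 * U0 * U1)


def test_he_polynomial_rejects_leftover_p():
    with pytest.raises(ValueError, match="embedding parameter"):
        HePolynomial(0, P * x)


def test_he_completeness_cubic_operator():
    """Sum of H_0..H_3 reproduces the p-expansion of N(sum p^j U_j)
    through p-order 3, for a degree-3 polynomial operator."""
    rng = random.Random(20140708)
    for _ in range(5):
        terms = _terms(*[sp.Integer(rng.randint(-3, 3)) * x**rng.randint(0, 2)
                         + rng.randint(-2, 2) for _ in range(4)])
        op = lambda F: F["U"] ** 3 + 2 * F["U"] ** 2 - F["U"]
        embedded = sum(P**j * terms[j]["U"] for j in range(4))
        full = sp.expand(op({"U": embedded}))
        for order in range(4):
            hn = he_polynomials_bruteforce(op, terms, order).expression
            assert _zero(hn - full.coeff(P, order))


def _random_poly_terms(rng, n_orders):
    def poly():
        return sum(sp.Integer(rng.randint(-3, 3)) * x**i * t**j
                   for i in range(3) for j in range(2))
    return [SeriesTerm(k, {"u": poly(), "rho": poly()}) for k in range(n_orders)]


@pytest.mark.parametrize("monomials", [
    ((sp.Integer(-1), (("u", 1), ("rho", 1))),),                      # bilinear
    ((sp.Integer(2), (("u", 0), ("rho", 1), ("rho", 1))),),           # trilinear
    ((sp.Integer(1), (("u", 0), ("rho", 2))),
     (sp.Integer(-2), (("rho", 0), ("u", 1), ("rho", 1))),),          # mixed sum
])
def test_convolution_matches_bruteforce(monomials):
    rng = random.Random(7)
    spec = ProductFormNonlinearity(monomials)
    op = spec.as_callable()
    for order in (0, 1, 3):
        terms = _random_poly_terms(rng, order + 1)
        conv = he_polynomials_convolution(spec, terms, order).expression
        brute = he_polynomials_bruteforce(op, terms, order).expression
        assert sp.expand(conv - brute) == 0


def test_convolution_order2_bilinear_has_two_summands():
    """At order 2 the bilinear convolution is the two-term cross sum
    u0_x * rho1_x + u1_x * rho0_x (times the coefficient)."""
    u0, u1, r0, r1 = [sp.Function(f)(x) for f in ("u0", "u1", "r0", "r1")]
    terms = [SeriesTerm(0, {"u": u0, "rho": r0}), SeriesTerm(1, {"u": u1, "rho": r1}),
             SeriesTerm(2, {"u": sp.Integer(0), "rho": sp.Integer(0)})]
    spec = ProductFormNonlinearity(((sp.Integer(-1), (("u", 1), ("rho", 1))),))
    got = he_polynomials_convolution(spec, terms, 1).expression
    want = -(sp.diff(u0, x) * sp.diff(r1, x) + sp.diff(u1, x) * sp.diff(r0, x))
    assert _zero(got - want)


def test_product_form_rejects_too_many_factors():
    with pytest.raises(ValueError):
        ProductFormNonlinearity(((sp.Integer(1),
                                  (("u", 0), ("u", 0), ("u", 0), ("u", 0))),))


# --------------------------------------------------------------------------
# hdm_solve
# --------------------------------------------------------------------------

def test_stationary_problem_has_zero_higher_orders():
    prob = GeneralProblem.single(sp.exp(-x))
    series = hdm_solve(prob, 3)
    assert series.terms[0]["U"] == sp.exp(-x)
    for k in range(1, 4):
        assert series.terms[k]["U"] == 0


def test_second_order_time_problem():
    """m=2 with L = d2/dx2 and zero initial velocity: first correction is
    the double time integral of u0''."""
    prob = GeneralProblem.single(sp.sin(x), linear_op=lambda e: sp.diff(e, x, 2),
                                 time_order=2)
    series = hdm_solve(prob, 2)
    assert _zero(series.terms[1]["U"] + sp.sin(x) * t**2 / 2)
    assert _zero(series.terms[2]["U"] - sp.sin(x) * t**4 / 24)


def test_forcing_enters_once_at_order_one():
    prob = GeneralProblem.single(sp.Integer(0), forcing=sp.exp(-x))
    series = hdm_solve(prob, 3)
    assert _zero(series.terms[1]["U"] - sp.exp(-x) * t)
    assert series.terms[2]["U"] == 0 and series.terms[3]["U"] == 0


def test_partial_series_on_integration_failure():
    # the forcing has no closed-form antiderivative, so order 1 must fail
    prob = GeneralProblem.single(sp.exp(-x), forcing=sp.exp(sp.tan(t)))
    with pytest.raises(IntegrationFailure) as exc:
        hdm_solve(prob, 2)
    assert exc.value.order == 1
    assert exc.value.partial is not None
    assert exc.value.partial.truncation == 0
    assert exc.value.partial.terms[0]["U"] == sp.exp(-x)


def test_series_orders_contiguous_invariant():
    with pytest.raises(ValueError, match="contiguous"):
        engine.HDMSeries(terms=[SeriesTerm(0, {"U": x}), SeriesTerm(2, {"U": x})],
                         truncation=1)


# --------------------------------------------------------------------------
# symbolic equality
# --------------------------------------------------------------------------

@pytest.mark.parametrize("e1,e2", [
    ((x + 1) ** 2, x**2 + 2 * x + 1),
    (sp.sin(x) ** 2 + sp.cos(x) ** 2, sp.Integer(1)),
    (sp.exp(x + t), sp.exp(x) * sp.exp(t)),
])
def test_symbolic_equal_identities(e1, e2):
    res = symbolic_equal(e1, e2)
    assert res.equal and res.method == "symbolic"


def test_symbolic_equal_detects_difference():
    res = symbolic_equal((x + 1) ** 2, x**2 + 2 * x)
    assert not res.equal


def test_symbolic_equal_disjoint_symbols_ambiguous():
    y, z = sp.symbols("y z")
    with pytest.raises(AmbiguityError):
        symbolic_equal(sp.exp(y) - sp.Rational(1, 3), sp.log(z))


def test_symbolic_equal_numeric_fallback_with_ranges():
    y = sp.Symbol("y")
    res = symbolic_equal(sp.sqrt(y**2), y, ranges={y: (0.5, 2.0)})
    assert res.equal  # true on the declared positive range
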
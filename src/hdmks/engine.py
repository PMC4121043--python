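"""Generic homotopy-decomposition recursion.

The method rewrites an evolution problem

    d^m U / dt^m = L(U) + N(U) + f(x, t)

as a Volterra integral equation using the Abel kernel (the one-integral
form of m-fold time integration), embeds the solution in a power series
of a homotopy parameter p, decomposes the nonlinearity into He's
polynomials H_n, and matches powers of p.  The result is an explicit
recursion: the order-0 term is the Taylor initial guess built from the
initial data, and each higher term is the Abel inverse of the previous
order's linear, nonlinear and (at order 1) forcing contributions.

Everything here is field-agnostic: a "problem" carries one or more
unknown fields (the Keller-Segel system has two, u and rho), and the
linear / nonlinear operators act on dictionaries mapping field names to
sympy expressions in ``x`` and ``t``.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from typing import Callable, Mapping, Sequence

import sympy as sp

from ._symbols import DEFAULT_RANGES, p as P, t, tau, x

__all__ = [
    "GeneralProblem",
    "SeriesTerm",
    "HDMSeries",
    "HePolynomial",
    "ProductFormNonlinearity",
    "IntegrationFailure",
    "AmbiguityError",
    "initial_guess",
    "abel_inverse",
    "he_polynomials_bruteforce",
    "he_polynomials_convolution",
    "hdm_solve",
    "symbolic_equal",
    "EqualityResult",
]

FieldMap = Mapping[str, sp.Expr]


class IntegrationFailure(RuntimeError):
    """Raised when a recursion integrand has no closed-form antiderivative.

    Carries the orders that *were* completed so the caller can inspect a
    partial series.
    """

    def __init__(self, order: int, integrand: sp.Expr, partial: "HDMSeries | None" = None):
        self.order = order
        self.integrand = integrand
        self.partial = partial
        super().__init__(
            f"symbolic integration failed at order {order}; "
            f"offending integrand: {integrand}"
        )


class AmbiguityError(ValueError):
    """Equality check cannot be decided: disjoint symbols, no ranges."""


# --------------------------------------------------------------------------
# problem specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneralProblem:
    """A time-order-m evolution problem for one or more unknown fields.

    Parameters
    ----------
    fields
        Names of the unknowns, e.g. ``("u", "rho")``.
    initial_data
        Per field, the Taylor coefficients of the solution at t=0:
        the i-th entry is the i-th time derivative at t=0.  Lengths
        between ``max(m-1, 1)`` and ``m`` are accepted; an omitted
        (m-1)-th coefficient is taken to be zero (the convention that
        the top initial derivative vanishes).
    linear_op
        Callable mapping a field dictionary to a field dictionary: the
        linear part of the right-hand side.  May couple fields.
    nonlinear
        Per field, either ``None``, a plain callable on a field
        dictionary (handled by the brute-force He construction), or a
        :class:`ProductFormNonlinearity` (handled by convolution).
    forcing
        Per field, a known source expression f(x, t); enters the
        recursion once, at order 1.
    time_order
        m, the order of the time derivative on the left-hand side.
    """

    fields: tuple[str, ...]
    initial_data: Mapping[str, Sequence[sp.Expr]]
    linear_op: Callable[[FieldMap], FieldMap]
    nonlinear: Mapping[str, object] = dc_field(default_factory=dict)
    forcing: Mapping[str, sp.Expr] = dc_field(default_factory=dict)
    time_order: int = 1

    def __post_init__(self):
        if self.time_order < 1:
            raise ValueError("time_order must be a positive integer")
        lo = max(self.time_order - 1, 1)
        for f in self.fields:
            if f not in self.initial_data:
                raise ValueError(f"missing initial data for field {f!r}")
            k = len(self.initial_data[f])
            if not lo <= k <= self.time_order:
                raise ValueError(
                    f"field {f!r}: expected {lo}..{self.time_order} initial "
                    f"Taylor coefficients, got {k}"
                )

    @classmethod
    def single(cls, initial_data, linear_op=None, nonlinear_op=None,
               forcing=sp.Integer(0), time_order=1, name="U"):
        """Convenience constructor for a scalar problem."""
        if not isinstance(initial_data, (list, tuple)):
            initial_data = [initial_data]
        lin = linear_op or (lambda F: sp.Integer(0))
        return cls(
            fields=(name,),
            initial_data={name: [sp.sympify(e) for e in initial_data]},
            linear_op=lambda F: {name: lin(F[name])},
            nonlinear={name: (lambda F: nonlinear_op(F[name])) if nonlinear_op else None},
            forcing={name: sp.sympify(forcing)},
            time_order=time_order,
        )


@dataclass(frozen=True)
class SeriesTerm:
    """One order of the homotopy series: an expression per field."""

    order: int
    fields: Mapping[str, sp.Expr]

    def __getitem__(self, name: str) -> sp.Expr:
        return self.fields[name]


@dataclass(frozen=True)
class HePolynomial:
    index: int
    expression: sp.Expr

    def __post_init__(self):
        if self.expression.has(P):
            raise ValueError(
                "He polynomial retained the embedding parameter p — the "
                "p-elimination step failed"
            )


@dataclass
class HDMSeries:
    """Ordered series terms 0..N plus the problem that produced them."""

    terms: list[SeriesTerm]
    truncation: int
    problem: object = None

    def __post_init__(self):
        orders = [tm.order for tm in self.terms]
        if orders != list(range(len(self.terms))):
            raise ValueError("series orders must be contiguous from 0")
        if self.truncation != len(self.terms) - 1:
            raise ValueError("truncation inconsistent with number of terms")

    @property
    def field_names(self) -> tuple[str, ...]:
        return tuple(self.terms[0].fields)

    def partial_sum(self, name: str, upto: int | None = None) -> sp.Expr:
        upto = self.truncation if upto is None else upto
        return sp.Add(*[tm[name] for tm in self.terms[: upto + 1]])

    def to_dict(self) -> dict:
        """JSON-ready serialization: srepr (machine) + str (human)."""
        return {
            "truncation": self.truncation,
            "fields": list(self.field_names),
            "terms": [
                {
                    "order": tm.order,
                    "exprs": {k: {"srepr": sp.srepr(v), "str": str(v)}
                              for k, v in tm.fields.items()},
                }
                for tm in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "HDMSeries":
        terms = [
            SeriesTerm(
                order=entry["order"],
                fields={k: sp.sympify(v["srepr"]) for k, v in entry["exprs"].items()},
            )
            for entry in data["terms"]
        ]
        return cls(terms=terms, truncation=data["truncation"])


@dataclass(frozen=True)
class ProductFormNonlinearity:
    """Sum of product monomials in the fields and their x-derivatives.

    Each monomial is ``(coefficient, ((field, dx_order), ...))`` and
    stands for  coefficient * prod_i  d^{dx_i} field_i / dx^{dx_i}.
    Products of up to three field factors are supported — enough for
    the chemotactic terms of the linear and quadratic sensitivities.
    """

    monomials: tuple[tuple[sp.Expr, tuple[tuple[str, int], ...]], ...]

    def __post_init__(self):
        for coef, factors in self.monomials:
            if not 1 <= len(factors) <= 3:
                raise ValueError("product-form monomials support 1..3 field factors")

    def as_callable(self) -> Callable[[FieldMap], sp.Expr]:
        def op(F: FieldMap) -> sp.Expr:
            out = sp.Integer(0)
            for coef, factors in self.monomials:
                term = coef
                for name, dxo in factors:
                    term *= sp.diff(F[name], x, dxo) if dxo else F[name]
                out += term
            return out
        return op


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def initial_guess(problem: GeneralProblem) -> dict[str, sp.Expr]:
    """Degree-(m-1) Taylor polynomial in t built from the initial data.

    For a first-order problem this is just the initial condition.
    """
    out = {}
    for f in problem.fields:
        data = list(problem.initial_data[f])
        while len(data) < problem.time_order:  # top coefficient defaults to 0
            data.append(sp.Integer(0))
        out[f] = sp.Add(
            *[t**k / sp.factorial(k) * sp.sympify(y) for k, y in enumerate(data)]
        )
    return out


def abel_inverse(integrand: sp.Expr, time_order: int = 1) -> sp.Expr:
    """Apply the Abel-kernel inverse of d^m/dt^m.

    Computes ``1/(m-1)! * int_0^t (t - s)^(m-1) * integrand(x, s) ds``
    in closed form.  The integrand may be written in ``t`` (it is
    evaluated at the integration variable internally).  The result
    vanishes at t = 0 by construction.
    """
    if time_order < 1:
        raise ValueError("time_order must be >= 1")
    body = sp.sympify(integrand).subs(t, tau)
    kernel = (t - tau) ** (time_order - 1) / sp.factorial(time_order - 1)
    result = sp.integrate(sp.expand(kernel * body), (tau, 0, t))
    if result.has(sp.Integral):
        raise IntegrationFailure(order=-1, integrand=integrand)
    return sp.expand(result)


def he_polynomials_bruteforce(nonlinear_op: Callable[[FieldMap], sp.Expr],
                              terms: Sequence[SeriesTerm],
                              order: int) -> HePolynomial:
    """He polynomial by its defining p-derivative.

    Builds N(sum_j p^j U_j) for every field, differentiates ``order``
    times with respect to the embedding parameter, divides by order!,
    and evaluates at p = 0.  Works for any operator smooth in its
    arguments; this is the authoritative path and the only one
    available for non-polynomial sensitivities.
    """
    if len(terms) <= order:
        raise ValueError(f"need series terms 0..{order}, got {len(terms)}")
    names = terms[0].fields.keys()
    embedded = {f: sp.Add(*[P**j * terms[j][f] for j in range(order + 1)])
                for f in names}
    expr = nonlinear_op(embedded)
    try:
        deriv = sp.diff(expr, P, order) if order else expr
    except Exception as exc:  # non-smooth operator
        raise ValueError(f"nonlinear operator not differentiable in p: {exc}") from exc
    return HePolynomial(order, sp.expand(deriv.subs(P, 0) / sp.factorial(order)))


def he_polynomials_convolution(nonlinear_spec: ProductFormNonlinearity,
                               terms: Sequence[SeriesTerm],
                               order: int) -> HePolynomial:
    """He polynomial by discrete convolution over term orders.

    For a product of k field factors the order-n polynomial is the sum
    over all compositions j_1 + ... + j_k = n of the factor product at
    those orders — no symbolic p-differentiation.  Agrees with
    :func:`he_polynomials_bruteforce` on its domain.
    """
    if not isinstance(nonlinear_spec, ProductFormNonlinearity):
        raise TypeError("convolution path requires a ProductFormNonlinearity")
    if len(terms) <= order:
        raise ValueError(f"need series terms 0..{order}, got {len(terms)}")

    def factor_at(name: str, dxo: int, j: int) -> sp.Expr:
        e = terms[j][name]
        return sp.diff(e, x, dxo) if dxo else e

    out = sp.Integer(0)
    for coef, factors in nonlinear_spec.monomials:
        k = len(factors)
        if k == 1:
            (f1, d1), = factors
            out += coef * factor_at(f1, d1, order)
        elif k == 2:
            (f1, d1), (f2, d2) = factors
            for j in range(order + 1):
                out += coef * factor_at(f1, d1, j) * factor_at(f2, d2, order - j)
        else:
            (f1, d1), (f2, d2), (f3, d3) = factors
            for j in range(order + 1):
                for kk in range(order - j + 1):
                    out += (coef * factor_at(f1, d1, j) * factor_at(f2, d2, kk)
                            * factor_at(f3, d3, order - j - kk))
    return HePolynomial(order, sp.expand(out))


def _he_term(nonlinear, terms, order) -> sp.Expr:
    if nonlinear is None:
        return sp.Integer(0)
    if isinstance(nonlinear, ProductFormNonlinearity):
        return he_polynomials_convolution(nonlinear, terms, order).expression
    return he_polynomials_bruteforce(nonlinear, terms, order).expression


def hdm_solve(problem: GeneralProblem, truncation: int,
              simplify_terms: bool = False) -> HDMSeries:
    """Run the homotopy-decomposition recursion up to the given order.

    Order 0 is the Taylor initial guess.  For n >= 1, each field's
    order-n term is the Abel inverse of the order-(n-1) linear
    contribution plus the order-(n-1) He polynomial of its
    nonlinearity, plus (at n = 1 only) the forcing term.  A symbolic
    integration failure at order k raises :class:`IntegrationFailure`
    carrying the partial series through order k-1.
    """
    if truncation < 0:
        raise ValueError("truncation must be >= 0")
    terms = [SeriesTerm(0, initial_guess(problem))]
    for k in range(1, truncation + 1):
        prev = terms[k - 1].fields
        lin = problem.linear_op(dict(prev))
        new = {}
        for f in problem.fields:
            integrand = sp.sympify(lin.get(f, 0))
            integrand += _he_term(problem.nonlinear.get(f), terms, k - 1)
            if k == 1:
                integrand += sp.sympify(problem.forcing.get(f, 0))
            try:
                expr = abel_inverse(integrand, problem.time_order)
            except IntegrationFailure:
                partial = HDMSeries(terms=terms, truncation=k - 1, problem=problem)
                raise IntegrationFailure(order=k, integrand=integrand, partial=partial)
            new[f] = sp.simplify(expr) if simplify_terms else expr
        terms.append(SeriesTerm(k, new))
    return HDMSeries(terms=terms, truncation=truncation, problem=problem)


# --------------------------------------------------------------------------
# symbolic equality with certificate
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EqualityResult:
    equal: bool
    method: str          # "symbolic" or "numeric"
    difference: sp.Expr  # the simplified difference (0 when equal symbolically)

    def __bool__(self) -> bool:
        return self.equal


def _canonical_zero(diff: sp.Expr) -> bool:
    d = sp.expand(diff)
    if d == 0:
        return True
    d = sp.collect(d, t)
    if sp.simplify(d) == 0:
        return True
    return sp.simplify(sp.expand_trig(sp.expand(diff))) == 0


def symbolic_equal(e1: sp.Expr, e2: sp.Expr,
                   ranges: Mapping[sp.Symbol, tuple[float, float]] | None = None,
                   n_points: int = 20, rel_tol: float = 1e-10,
                   seed: int = 20140708) -> EqualityResult:
    """Decide whether two expressions are equal.

    Canonical route: expand, collect in t, simplify (with trig/exp
    rewriting) and test the difference against zero.  If simplification
    cannot settle it, fall back to evaluation at ``n_points`` random
    points drawn from ``ranges`` (defaults provided for the package's
    canonical symbols) and label the verdict ``"numeric"``.
    """
    e1, e2 = sp.sympify(e1), sp.sympify(e2)
    diff = e1 - e2
    if _canonical_zero(diff):
        return EqualityResult(True, "symbolic", sp.Integer(0))

    syms = sorted(diff.free_symbols, key=lambda s: s.name)
    if not syms:  # purely numeric difference that did not simplify to 0
        val = complex(sp.N(diff))
        return EqualityResult(abs(val) <= rel_tol, "numeric", sp.nsimplify(diff, rational=False))

    ranges = dict(DEFAULT_RANGES) | dict(ranges or {})
    missing = [s for s in syms if s not in ranges]
    if missing:
        shared = e1.free_symbols & e2.free_symbols
        if not shared:
            raise AmbiguityError(
                f"expressions share no symbols and no ranges declared for {missing}"
            )
        raise AmbiguityError(f"no sampling range declared for symbols {missing}")

    rng = random.Random(seed)
    f_diff = sp.lambdify(syms, diff, "math")
    f1 = sp.lambdify(syms, e1, "math")
    f2 = sp.lambdify(syms, e2, "math")
    for _ in range(max(n_points, 20)):
        pt = [rng.uniform(*ranges[s]) for s in syms]
        try:
            dv, v1, v2 = f_diff(*pt), f1(*pt), f2(*pt)
        except (OverflowError, ValueError, ZeroDivisionError):
            continue
        scale = max(abs(v1), abs(v2), 1.0)
        if abs(dv) > rel_tol * scale:
            return EqualityResult(False, "numeric", sp.simplify(diff))
    return EqualityResult(True, "numeric", sp.simplify(diff))
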
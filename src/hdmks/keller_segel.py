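"""Keller-Segel model definitions and the chemotaxis-specific recursion.

The one-dimensional minimal Keller-Segel system couples the amoebae
density u(x, t) and the chemoattractant concentration rho(x, t):

    u_t   = a u_xx - ( u * chi'(rho) * rho_x )_x
    rho_t = b rho_xx + c u - d rho

on a bounded interval with zero-flux (Neumann) boundaries.  a and b are
diffusivities, c the chemical production rate, d its decay rate, and
chi(rho) the sensitivity function describing how the cells perceive the
chemical.  The worked sensitivities are chi = 1 (no chemotaxis — the
system decouples), chi = rho, and chi = rho^2; any other smooth chi is
supported through the generic brute-force He-polynomial path.

Two sign variants of the chemotactic term are carried throughout.  The
``conservative`` variant is the divergence form written above, the one a
zero-flux boundary problem actually conserves mass under.  The
``as_printed`` variant reproduces the expanded forms in which the term
circulates in the semi-analytic literature for chi = rho and chi = rho^2
(the sign of the u * rho_xx group is flipped relative to the product
rule); it is the variant under which the fixture library's series terms
are generated.  The two coincide for constant chi.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping

import sympy as sp

from . import engine
from ._symbols import a as A, b as B, c as C, d as D, m as M, n as N_, t, x
from .engine import GeneralProblem, HDMSeries, ProductFormNonlinearity, SeriesTerm

__all__ = [
    "KSParameters",
    "SensitivitySpec",
    "KSDomain",
    "KSModel",
    "chemotactic_nonlinearity",
    "chemotactic_operator",
    "chemotactic_integrand",
    "build_problem",
    "solve",
    "EXAMPLES",
    "get_example",
    "EXAMPLE_IDS",
]

RHO = sp.Symbol("rho", positive=True)  # placeholder for generic chi(rho)


@dataclass(frozen=True)
class KSParameters:
    """Rate constants and initial amplitudes.

    ``amp_u`` and ``amp_rho`` are the initial amplitudes of u and rho
    (rendered as ``m`` and ``n`` in symbolic output, matching the usual
    notation for these worked examples).
    """

    a: float
    b: float
    c: float
    d: float
    amp_u: float
    amp_rho: float

    def __post_init__(self):
        import math
        for name in ("a", "b"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"parameter {name} must be a positive finite real, got {v}")
        # production/decay may be switched off for conservation diagnostics
        for name in ("c", "d"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"parameter {name} must be a nonnegative finite real, got {v}")
        for name in ("amp_u", "amp_rho"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def exact_map(self) -> dict[sp.Symbol, sp.Rational]:
        """Substitution map with values as exact rationals."""
        vals = (self.a, self.b, self.c, self.d, self.amp_u, self.amp_rho)
        return {s: sp.nsimplify(v, rational=True)
                for s, v in zip((A, B, C, D, M, N_), vals)}

    def float_map(self) -> dict[sp.Symbol, float]:
        vals = (self.a, self.b, self.c, self.d, self.amp_u, self.amp_rho)
        return {s: float(v) for s, v in zip((A, B, C, D, M, N_), vals)}


@dataclass(frozen=True)
class SensitivitySpec:
    """Sensitivity function chi(rho) plus the sign convention in use."""

    form: str = "constant"          # constant | linear | quadratic | generic
    sign_variant: str = "as_printed"  # as_printed | conservative
    chi_expr: sp.Expr | None = None   # required for form == "generic", in RHO

    def __post_init__(self):
        if self.form not in {"constant", "linear", "quadratic", "generic"}:
            raise ValueError(f"unknown sensitivity form {self.form!r}")
        if self.sign_variant not in {"as_printed", "conservative"}:
            raise ValueError(f"unknown sign variant {self.sign_variant!r}")
        if self.form == "generic" and self.chi_expr is None:
            raise ValueError("generic sensitivity needs chi_expr (expression in rho)")

    @property
    def chi(self) -> sp.Expr:
        return {"constant": sp.Integer(1), "linear": RHO,
                "quadratic": RHO**2}.get(self.form, self.chi_expr)

    @property
    def chi_prime(self) -> sp.Expr:
        return sp.diff(self.chi, RHO)


@dataclass(frozen=True)
class KSDomain:
    """Bounded interval with zero-flux Neumann boundaries at both ends."""

    alpha: float = -10.0
    beta: float = 10.0

    def __post_init__(self):
        if not self.alpha < self.beta:
            raise ValueError("domain requires alpha < beta")

    @property
    def length(self) -> float:
        return self.beta - self.alpha


@dataclass(frozen=True)
class KSModel:
    init_u: sp.Expr
    init_rho: sp.Expr
    sensitivity: SensitivitySpec = dc_field(default_factory=SensitivitySpec)
    domain: KSDomain = dc_field(default_factory=KSDomain)
    parameters: KSParameters | None = None

    def with_variant(self, sign_variant: str) -> "KSModel":
        return replace(self, sensitivity=replace(self.sensitivity, sign_variant=sign_variant))


# --------------------------------------------------------------------------
# chemotactic term
# --------------------------------------------------------------------------

_PRODUCT_FORMS = {
    # -u_x rho_x + u rho_xx   (expanded form as circulated for chi = rho)
    ("linear", "as_printed"): (
        (sp.Integer(-1), (("u", 1), ("rho", 1))),
        (sp.Integer(1), (("u", 0), ("rho", 2))),
    ),
    # -(u rho_x)_x = -u_x rho_x - u rho_xx
    ("linear", "conservative"): (
        (sp.Integer(-1), (("u", 1), ("rho", 1))),
        (sp.Integer(-1), (("u", 0), ("rho", 2))),
    ),
    # -2 rho u_x rho_x + 2 u rho rho_xx + 2 u rho_x^2
    ("quadratic", "as_printed"): (
        (sp.Integer(-2), (("rho", 0), ("u", 1), ("rho", 1))),
        (sp.Integer(2), (("u", 0), ("rho", 0), ("rho", 2))),
        (sp.Integer(2), (("u", 0), ("rho", 1), ("rho", 1))),
    ),
    # -(2 u rho rho_x)_x = -2 rho u_x rho_x - 2 u rho_x^2 - 2 u rho rho_xx
    ("quadratic", "conservative"): (
        (sp.Integer(-2), (("rho", 0), ("u", 1), ("rho", 1))),
        (sp.Integer(-2), (("u", 0), ("rho", 0), ("rho", 2))),
        (sp.Integer(-2), (("u", 0), ("rho", 1), ("rho", 1))),
    ),
}


def chemotactic_nonlinearity(sensitivity: SensitivitySpec):
    """Nonlinear operator of the u-equation for the configured chi.

    Returns ``None`` for constant chi (the term vanishes identically), a
    :class:`~hdmks.engine.ProductFormNonlinearity` for the linear and
    quadratic sensitivities (convolution path), or a plain callable for
    a generic chi (brute-force path; conservative variant only — no
    expanded printed form exists for a generic sensitivity).
    """
    if sensitivity.form == "constant":
        return None
    key = (sensitivity.form, sensitivity.sign_variant)
    if key in _PRODUCT_FORMS:
        return ProductFormNonlinearity(_PRODUCT_FORMS[key])
    if sensitivity.sign_variant == "as_printed":
        raise ValueError(
            "generic sensitivity has no as_printed expansion; use the "
            "conservative variant"
        )
    chi_p = sensitivity.chi_prime

    def op(F):
        return -sp.diff(F["u"] * chi_p.subs(RHO, F["rho"]) * sp.diff(F["rho"], x), x)

    return op


def chemotactic_operator(sensitivity: SensitivitySpec,
                         u_expr: sp.Expr, rho_expr: sp.Expr) -> sp.Expr:
    """The full (not order-by-order) chemotactic term applied to given fields."""
    nl = chemotactic_nonlinearity(sensitivity)
    if nl is None:
        return sp.Integer(0)
    if isinstance(nl, ProductFormNonlinearity):
        return nl.as_callable()({"u": u_expr, "rho": rho_expr})
    return nl({"u": u_expr, "rho": rho_expr})


def chemotactic_integrand(model: KSModel, terms: list[SeriesTerm], order: int) -> sp.Expr:
    """Order-n chemotactic contribution to the u-recursion (uses terms 0..n-1)."""
    if order < 1:
        raise ValueError("chemotactic contributions start at order 1")
    nl = chemotactic_nonlinearity(model.sensitivity)
    if nl is None:
        return sp.Integer(0)
    if isinstance(nl, ProductFormNonlinearity):
        return engine.he_polynomials_convolution(nl, terms, order - 1).expression
    return engine.he_polynomials_bruteforce(nl, terms, order - 1).expression


# --------------------------------------------------------------------------
# problem assembly and solving
# --------------------------------------------------------------------------

def build_problem(model: KSModel, numeric: bool = False) -> GeneralProblem:
    """Assemble the coupled first-order HDM problem for u and rho.

    With ``numeric=True`` the model's parameter values are substituted
    (as exact rationals) into the operators and initial conditions, which
    keeps high-order recursions cheap.
    """
    subs = {}
    if numeric:
        if model.parameters is None:
            raise ValueError("numeric=True requires model.parameters")
        subs = model.parameters.exact_map()
    av, bv, cv, dv = (s.subs(subs) for s in (A, B, C, D))

    def linear(F):
        return {
            "u": av * sp.diff(F["u"], x, 2),
            "rho": bv * sp.diff(F["rho"], x, 2) + cv * F["u"] - dv * F["rho"],
        }

    return GeneralProblem(
        fields=("u", "rho"),
        initial_data={
            "u": [sp.sympify(model.init_u).subs(subs)],
            "rho": [sp.sympify(model.init_rho).subs(subs)],
        },
        linear_op=linear,
        nonlinear={"u": chemotactic_nonlinearity(model.sensitivity), "rho": None},
        time_order=1,
    )


def solve(model: KSModel, truncation: int, numeric: bool = False) -> HDMSeries:
    """Run the homotopy-decomposition recursion for a Keller-Segel model."""
    series = engine.hdm_solve(build_problem(model, numeric=numeric), truncation)
    series.problem = model
    return series


# --------------------------------------------------------------------------
# worked-example registry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KSExample:
    example_id: str
    description: str
    model: KSModel
    default_truncation: int = 4


def _make_examples() -> dict[str, KSExample]:
    gauss_u, gauss_r = M * sp.exp(-(x**2)), N_ * sp.exp(-(x**2))
    expo_u, expo_r = M * sp.exp(-x), N_ * sp.exp(-x)
    sine_u, sine_r = M * sp.sin(x), N_ * sp.sin(x)
    base = dict(c=1.0, d=2.0, amp_u=120.0, amp_rho=160.0)
    p1 = KSParameters(a=0.5, b=3.0, **base)
    p2 = KSParameters(a=0.5, b=0.001, **base)
    ex = {
        "ex1": KSExample(
            "ex1",
            "constant sensitivity chi = 1, Gaussian initial data (decoupled u)",
            KSModel(gauss_u, gauss_r, SensitivitySpec("constant"),
                    KSDomain(-10, 10), p1),
            default_truncation=3,
        ),
        "ex2_case1": KSExample(
            "ex2_case1",
            "linear sensitivity chi = rho, exponential initial data "
            "(chemotaxis cancels order by order; u sums to m*exp(a t - x))",
            KSModel(expo_u, expo_r, SensitivitySpec("linear"),
                    KSDomain(0, 20), p2),
            default_truncation=4,
        ),
        "ex2_case2": KSExample(
            "ex2_case2",
            "linear sensitivity chi = rho, Gaussian initial data",
            KSModel(gauss_u, gauss_r, SensitivitySpec("linear"),
                    KSDomain(-10, 10), p2),
            default_truncation=2,
        ),
        "ex3": KSExample(
            "ex3",
            "quadratic sensitivity chi = rho^2, sinusoidal initial data",
            KSModel(sine_u, sine_r, SensitivitySpec("quadratic"),
                    KSDomain(-float(sp.pi), float(sp.pi)), p2),
            default_truncation=2,
        ),
    }
    return ex


EXAMPLES: Mapping[str, KSExample] = _make_examples()
EXAMPLE_IDS = tuple(EXAMPLES)


def get_example(example_id: str, sign_variant: str = "as_printed") -> KSModel:
    if example_id not in EXAMPLES:
        raise KeyError(f"unknown example {example_id!r}; choose from {EXAMPLE_IDS}")
    return EXAMPLES[example_id].model.with_variant(sign_variant)
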
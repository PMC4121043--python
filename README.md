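# hdmks

Semi-analytic series solutions of the one-dimensional Keller–Segel
chemotaxis system by the homotopy decomposition method, with an
independent finite-difference oracle.

## The problem

The minimal Keller–Segel model couples the density u(x, t) of
chemotactic cells (slime-mold amoebae) to the concentration ρ(x, t) of
the chemical that attracts them:

    u_t = a u_xx − ( u · χ′(ρ) · ρ_x )_x
    ρ_t = b ρ_xx + c u − d ρ

on a bounded interval with zero-flux boundaries. The sensitivity
function χ(ρ) encodes how the cells perceive the chemical; the classic
normalized choices χ = 1, ρ, ρ² are built in and any smooth χ is
accepted. No closed-form solution of the coupled system is known, so
semi-analytic series are a standard way to study its short-time
behaviour.

The homotopy decomposition method converts the system into a Volterra
integral equation via the Abel kernel (the one-integral form of m-fold
time integration), expands the solution in a homotopy parameter p,
decomposes the nonlinear chemotactic term into He polynomials
Hₙ = (1/n!) ∂ⁿ/∂pⁿ N(Σ pʲUⱼ)|₍p=0₎, and matches powers of p. This
yields an explicit recursion producing symbolic series terms
uₙ(x, t), ρₙ(x, t), implemented here on top of sympy.

The package is for anyone who wants to *check*, extend, or stress-test
such series solutions rather than take them on faith: every term is
regenerated from the recursion, compared against a transcribed fixture
library, and validated numerically against a conservative
finite-difference solver.

## Worked example

Linear sensitivity χ = ρ with exponential initial data
u(x,0) = m e⁻ˣ, ρ(x,0) = n e⁻ˣ:

    $ hdmks solve --example ex2_case1 --order 3

    u_0 = m*exp(-x)
    rho_0 = n*exp(-x)
    u_1 = a*m*t*exp(-x)
    rho_1 = b*n*t*exp(-x) + c*m*t*exp(-x) - d*n*t*exp(-x)
    u_2 = a**2*m*t**2*exp(-x)/2
    ...
    u_3 = a**3*m*t**3*exp(-x)/6

The chemotactic contribution cancels order by order for this data, so
the u-terms follow the factorial pattern uₙ = m e⁻ˣ (a t)ⁿ/n!, whose
sum is the closed form u = m e^{a t − x}. With the example parameters
(m = 120, a = 0.5) the partial sums at x = 2.5, t = 5 — where
x = a t — converge to 120, the initial amplitude:

```python
>>> import hdmks
>>> from hdmks._symbols import x, t
>>> s = hdmks.solve(hdmks.get_example("ex2_case1"), 30, numeric=True)
>>> sum(float(tm["u"].subs({x: 2.5, t: 5})) for tm in s.terms)
119.9999999999506
```

Fixture verification regenerates every transcribed series term and
reports exact matches and known discrepancies — for the quadratic
sensitivity χ = ρ² the published order-1 u-term is internally
inconsistent, and the report says so with the symbolic difference
instead of passing or failing silently:

    $ hdmks fixtures --example ex3

    fixture verification — ex3 (orders <= 2)
      rho_1: match [symbolic]
      u_1: known_discrepancy [numeric]  difference = 2*m*n**2*t*sin(x)*cos(2*x); corrected reading matches: True
      ...
      -> 1/4 exact matches; report OK

The finite-difference oracle cross-checks a truncated series at short
times (conservative sign variant, 401-point method-of-lines grid):

    $ hdmks compare --example ex1 --order 4 --t-max 0.1

reports a maximum normalized difference of ~7e-5 for the u field.

Other subcommands: `hdmks eval` (CSV of the series on a space–time
grid, with per-point validity flags) and `hdmks solve --out` /
`--series-in` (JSON serialization round-trip). See
[docs/methods.md](docs/methods.md) for the model, the sign-convention
question, series-validity diagnostics and the oracle design.

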
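# Methods

## Model

The package works with the minimal one-dimensional Keller–Segel system
for the density of chemotactic cells (amoebae) u(x, t) and the
concentration of the chemoattractant ρ(x, t):

    u_t   = a u_xx − ( u · χ′(ρ) · ρ_x )_x
    ρ_t   = b ρ_xx + c u − d ρ

on a bounded interval (α, β) with zero-flux Neumann boundaries
(u_x = ρ_x = 0 at both ends) and smooth initial data u₀(x), ρ₀(x).
The parameters, all dimensionless here, are

| symbol | meaning                        | worked-example values |
|--------|--------------------------------|-----------------------|
| a      | cell diffusivity               | 0.5                   |
| b      | chemical diffusivity           | 3 or 0.001            |
| c      | chemical production rate       | 1                     |
| d      | chemical decay rate            | 2                     |
| m, n   | initial amplitudes of u, ρ     | 120, 160              |

χ(ρ) is the sensitivity function describing the cells' response to the
chemical; the worked cases are χ = 1 (no chemotaxis — u decouples),
χ = ρ, and χ = ρ²; any other smooth χ is accepted through the generic
operator path. Validation allows c = d = 0 so the pure-transport
conservation structure can be checked; a and b must stay positive.

## Two sign conventions for the chemotactic term

Expanding the divergence form for χ = ρ gives
−(u ρ_x)_x = −u_x ρ_x − u ρ_xx. The expanded forms in which the
χ = ρ and χ = ρ² worked examples circulate instead carry
−u_x ρ_x **+** u ρ_xx (and the analogous signs for χ = ρ²). Both
variants are implemented end to end:

* `as_printed` — reproduces the published expansions term for term; the
  fixture library is generated under it. Not a divergence-form PDE for
  χ ≠ const.
* `conservative` — the self-consistent divergence form; the only
  variant the finite-difference oracle accepts, because zero-flux mass
  conservation is a property of the flux form.

The two coincide for constant χ. The difference is a genuine model
difference, and `compare_series_fd` quantifies it (it is order one
within milliseconds of model time for the Gaussian χ = ρ case).

## The homotopy-decomposition recursion

A problem d^m U/dt^m = L(U) + N(U) + f is converted to a Volterra
equation with the Abel kernel — the single-integral form of m-fold time
integration,

    (I_m g)(t) = 1/(m−1)! ∫₀ᵗ (t−s)^{m−1} g(s) ds,

the solution is embedded as U = Σ pⁿ Uₙ in a homotopy parameter
p ∈ (0, 1], the nonlinearity is decomposed into He polynomials

    Hₙ = (1/n!) ∂ⁿ/∂pⁿ N(Σⱼ pʲ Uⱼ) |_{p=0},

and powers of p are matched. The resulting recursion, implemented in
`hdmks.engine`, is

    U₀ = T(x,t)                 (Taylor polynomial of the initial data)
    Uₙ = I_m [ L(Uₙ₋₁) + Hₙ₋₁ + δ_{n,1} f ].

Two constructions of Hₙ are provided: the defining p-derivative
(`he_polynomials_bruteforce`, works for any smooth operator, e.g.
χ = log ρ) and a discrete convolution over term orders for product-form
nonlinearities of up to three field factors
(`he_polynomials_convolution`, the default for χ = ρ and χ = ρ²). The
two are asserted equivalent on seeded random instances; the He sum is
indexed from n = 0 — that is the indexing under which every worked
term is reproduced.

For m ≥ 2 the package follows the convention that the (m−1)-th time
derivative at t = 0 vanishes unless a top Taylor coefficient is
supplied explicitly; the Keller–Segel system is first order in time, so
this only affects the generic engine.

## Fixture library and known discrepancies

`data/printed_terms.json` transcribes the published series terms of the
three worked examples. Regenerating them with the `as_printed`
recursion gives, symbolically:

* χ = 1, Gaussian data: all six terms reproduced (one typographic token
  in the order-3 ρ term is read as 4x⁴; see the fixture note).
* χ = ρ, exponential data: u₁..u₄ and ρ₁..ρ₄ reproduced; the u-series
  is m e^{−x} (a t)ⁿ/n!, which sums to the closed form m e^{a t − x}.
* χ = ρ, Gaussian data: all four printed terms reproduced.
* χ = ρ², sinusoidal data: ρ₁ reproduced. The printed u₁ contains
  cos²x where the recursion yields sin²x — under *either* sign variant
  — and is stored with `status=discrepant`; the verification report
  shows the symbolic difference rather than passing or failing
  silently. Seeding the ρ-recursion with the *printed* u₁ reproduces
  the printed ρ₂ up to a single ambiguous monomial (read c·m·n², not
  the literal c·n·m²); u₂ inherits the u₁ discrepancy.

Symbolic equality uses expand → collect-in-t → simplify (with
trig/exponential rewriting); when simplification cannot settle a
difference, the verdict falls back to evaluation at ≥20 seeded random
points (relative tolerance 1e−10) and is labelled "numeric".

## Series evaluation and validity

The truncated series is asymptotic in t, not globally convergent. For
Gaussian data the u-series has convergence radius t ≈ 1/(4a) and the
ρ-series t ≈ 1/(4b) (the heat series of a Gaussian breaks down where
1 + 4·diffusivity·t changes character). With b = 3 that is t ≈ 0.083:
the order-4 ρ partial sum of the constant-χ example *diverges* from
the true solution at t = 0.1, and adding terms makes it worse. The
evaluator therefore flags every grid point where the magnitude of the
last retained term exceeds the previous one (or where evaluation
overflows); no validity radius is invented beyond that honest
per-point heuristic. At the figure slices used for plotting (t = 5)
the polynomial-in-t terms are far outside the validity region for the
Gaussian/sinusoidal cases — the flags say so — while the exponential
χ = ρ case converges for all t.

## Finite-difference oracle

`reference_fd` is an independent method-of-lines solver used to
validate the series at short times. Space is discretized on a uniform
grid (default 401 points) with all fluxes — diffusive and chemotactic
— evaluated at cell faces and differenced in conservation form;
boundary nodes are half-cells with zero boundary-face flux, which makes
the trapezoidal mass of u exactly conserved by the spatial scheme when
c = d = 0 (measured drift ~1e−15, i.e. integrator-level). Time
integration is scipy's BDF with a banded Jacobian sparsity pattern,
rtol 1e−8 / atol 1e−10. Verified properties: cosine-mode heat decay
exact to <1e−4 at 401 points, second-order grid convergence (error
ratio ≈4 per mesh halving), uniform equilibria (c u* = d ρ*)
stationary.

The unbounded-looking initial data (Gaussians, e^{−x}, sin x) are posed
on wide truncated intervals — [−10, 10] for Gaussians, [0, 20] for the
exponential, [−π, π] for the sinusoid — where the data decay to ≲1e−8
at the walls; the boundary perturbation is part of the reported error
budget. Oracle comparisons are restricted to short times (default
t ≤ 0.1): a 4-term series cannot be expected to track t = 5 dynamics.
Differences are normalized by the per-field maximum |oracle value| over
the comparison window, because a pointwise relative error is undefined
on the decaying tails. Measured at order 4 for the constant-χ example:
u agrees to 6.6e−5 for t ≤ 0.1; ρ agrees to ≤1e−3 only within its
convergence window (t ≲ 0.02) and is flagged divergent at t = 0.1, as
discussed above.

The conservative χ = ρ Gaussian case with full production/decay is
strongly aggregating; the stiff integrator stops early there and the
solver returns the snapshots it reached with a blow-up flag — failure
is reported, not hidden.

## Problem sizes and numerical choices

Symbolic runs use truncation N = 3–4 (the orders for which printed
terms exist; default 4, configurable). The closed-form-limit check
sums the exponential-case series with exact rational parameters until
the increment at (x, t) = (2.5, 5) falls below 1e−9 (21 terms). Random
property checks (He-polynomial equivalence, completeness) use small
integer-coefficient polynomials in x and t with a fixed seed
(20140708) for reproducibility.

## Limitations

* No convergence proofs or error bounds — diagnostics are empirical
  (term-ratio flags, oracle comparison, residual t-coefficients).
* No series acceleration (Padé or otherwise); partial sums are used as
  printed.
* The quadratic-sensitivity printed u-terms cannot be reconciled with
  any integrand variant tried; the package reports the discrepancy and
  does not guess the intended expression.
* One spatial dimension only; no fractional time orders.
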
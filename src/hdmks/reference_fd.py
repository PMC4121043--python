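"""Independent numerical oracle: method-of-lines finite differences.

Discretizes the full Keller-Segel boundary-value problem on a uniform
grid with zero-flux Neumann boundaries and integrates the resulting ODE
system with a stiff solver.  Both the diffusive and the chemotactic
fluxes are evaluated at cell faces and differenced in conservation
form, with half-cells at the two boundary nodes; the boundary face
fluxes are identically zero.  This makes the discrete trapezoidal mass
of u exactly conserved (up to time-integrator error) whenever the
production and decay terms are switched off — the structural invariant
the Neumann problem implies.

The oracle requires the conservative chemotactic variant (the expanded
as-printed variants of the nonlinear examples are not divergence-form
PDEs and are excluded); for constant sensitivity the variants coincide
and either is accepted.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import scipy.sparse
import sympy as sp
from scipy.integrate import solve_ivp

from ._symbols import x
from .engine import HDMSeries
from .keller_segel import KSModel, KSParameters, RHO
from .series_eval import EvalGrid, evaluate

__all__ = ["FDConfig", "FDSolution", "fd_solve", "compare_series_fd"]


@dataclass(frozen=True)
class FDConfig:
    n_points: int = 401
    t_end: float = 0.1
    t_snapshots: tuple[float, ...] | None = None  # default: 5 equispaced incl. t_end
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    method: str = "BDF"

    def __post_init__(self):
        if self.n_points < 11:
            raise ValueError("n_points must be >= 11")
        for tol in (self.rel_tol, self.abs_tol):
            if not 0 < tol <= 1e-2:
                raise ValueError("tolerances must lie in (0, 1e-2]")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")

    def snapshots(self) -> np.ndarray:
        if self.t_snapshots is not None:
            return np.asarray(self.t_snapshots, float)
        return np.linspace(0.0, self.t_end, 5)


@dataclass
class FDSolution:
    x_grid: np.ndarray
    t_snapshots: np.ndarray
    u_field: np.ndarray      # shape (n_t, n_x)
    rho_field: np.ndarray
    mass_u: np.ndarray       # trapezoidal integral of u per snapshot
    blow_up: bool = False
    message: str = ""


def _chi_prime_fn(model: KSModel):
    form = model.sensitivity.form
    if form == "constant":
        return lambda r: np.zeros_like(r)
    if form == "linear":
        return lambda r: np.ones_like(r)
    if form == "quadratic":
        return lambda r: 2.0 * r
    return sp.lambdify(RHO, model.sensitivity.chi_prime, "numpy")


def _jac_sparsity(n: int) -> scipy.sparse.spmatrix:
    band = scipy.sparse.diags([1.0, 1.0, 1.0], [-1, 0, 1], shape=(n, n))
    one = scipy.sparse.identity(n, dtype=float)
    return scipy.sparse.bmat([[band, band], [one + band, band]], format="csr")


def fd_solve(model: KSModel, config: FDConfig,
             params: KSParameters | None = None) -> FDSolution:
    """Integrate the Keller-Segel system by the method of lines."""
    if model.sensitivity.form != "constant" and \
            model.sensitivity.sign_variant != "conservative":
        raise ValueError(
            "the finite-difference oracle solves the divergence-form PDE; "
            "use the conservative sign variant"
        )
    params = params or model.parameters
    if params is None:
        raise ValueError("numeric parameters required")

    xs = np.linspace(model.domain.alpha, model.domain.beta, config.n_points)
    dx = xs[1] - xs[0]
    pm = params.float_map()
    u0 = np.asarray(sp.lambdify(x, sp.sympify(model.init_u).subs(pm), "numpy")(xs),
                    dtype=float) * np.ones_like(xs)
    r0 = np.asarray(sp.lambdify(x, sp.sympify(model.init_rho).subs(pm), "numpy")(xs),
                    dtype=float) * np.ones_like(xs)
    av, bv, cv, dv = params.a, params.b, params.c, params.d
    chi_p = _chi_prime_fn(model)
    n = xs.size

    def rhs(_t, y):
        u, r = y[:n], y[n:]
        # face fluxes (n-1 interior faces); boundary faces carry zero flux
        du_face = np.diff(u) / dx
        dr_face = np.diff(r) / dx
        ubar = 0.5 * (u[:-1] + u[1:])
        rbar = 0.5 * (r[:-1] + r[1:])
        flux_u = av * du_face - ubar * chi_p(rbar) * dr_face
        flux_r = bv * dr_face
        dudt = np.empty_like(u)
        drdt = np.empty_like(r)
        dudt[1:-1] = np.diff(flux_u) / dx
        drdt[1:-1] = np.diff(flux_r) / dx
        dudt[0] = flux_u[0] / (dx / 2)      # half-cell closure at the walls
        dudt[-1] = -flux_u[-1] / (dx / 2)
        drdt[0] = flux_r[0] / (dx / 2)
        drdt[-1] = -flux_r[-1] / (dx / 2)
        drdt += cv * u - dv * r
        return np.concatenate([dudt, drdt])

    snaps = config.snapshots()
    sol = solve_ivp(
        rhs, (0.0, config.t_end), np.concatenate([u0, r0]),
        method=config.method, t_eval=snaps,
        rtol=config.rel_tol, atol=config.abs_tol,
        jac_sparsity=_jac_sparsity(n),
    )
    u_field = sol.y[:n].T
    rho_field = sol.y[n:].T
    mass = np.trapezoid(u_field, xs, axis=1)
    return FDSolution(
        x_grid=xs, t_snapshots=sol.t, u_field=u_field, rho_field=rho_field,
        mass_u=mass, blow_up=(sol.status != 0), message=sol.message,
    )


def compare_series_fd(series: HDMSeries, model: KSModel, config: FDConfig,
                      t_max: float | None = None,
                      params: KSParameters | None = None) -> dict:
    """Max/mean differences between the truncated series and the oracle.

    Differences are normalized by the max |oracle value| of each field
    over the comparison window (a pointwise relative error is
    meaningless on the decaying tails of the worked initial data).
    Snapshots above ``t_max`` are excluded.
    """
    params = params or model.parameters
    fd = fd_solve(model, config, params)
    if fd.blow_up:
        raise RuntimeError(f"oracle integration failed: {fd.message}")
    t_max = config.t_end if t_max is None else t_max
    keep = fd.t_snapshots <= t_max + 1e-12
    ts = fd.t_snapshots[keep]
    grid = EvalGrid(tuple(fd.x_grid), tuple(ts))
    ev = evaluate(series, params, grid)
    report: dict = {"t_max": float(t_max), "truncation": series.truncation,
                    "n_points": int(fd.x_grid.size), "fields": {}}
    for name, s_vals, f_vals in (("u", ev.u_values, fd.u_field[keep].T),
                                 ("rho", ev.rho_values, fd.rho_field[keep].T)):
        scale = float(np.max(np.abs(f_vals)))
        diff = np.abs(s_vals - f_vals) / (scale if scale > 0 else 1.0)
        report["fields"][name] = {
            "max_rel_diff": float(np.max(diff)),
            "mean_rel_diff": float(np.mean(diff)),
            "scale": scale,
        }
    return report
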
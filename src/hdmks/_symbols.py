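"""Canonical symbols shared across the package.

``a, b, c, d`` are the Keller-Segel rate constants (declared positive so
sympy can cancel exponentials aggressively); ``m, n`` are the initial
amplitudes of the cell density and the chemoattractant.  ``p`` is the
homotopy embedding parameter and exists only transiently inside the
He-polynomial construction.
"""
import sympy as sp

x, t, tau = sp.symbols("x t tau", real=True)
p = sp.Symbol("p")

a, b, c, d = sp.symbols("a b c d", positive=True)
m, n = sp.symbols("m n", real=True)

#: default sampling ranges for the numeric equality fallback
DEFAULT_RANGES = {
    x: (-2.0, 2.0),
    t: (0.05, 1.0),
    a: (0.1, 2.0),
    b: (0.1, 2.0),
    c: (0.1, 2.0),
    d: (0.1, 2.0),
    m: (0.1, 2.0),
    n: (0.1, 2.0),
}
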
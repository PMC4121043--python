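{
  "comment": "Verbatim transcriptions of the worked-example series terms (symbols x, t, a, b, c, d, m, n). status=consistent: the as-printed recursion reproduces the term symbolically. status=discrepant: it does not; a note documents the inconsistency and, where a self-consistent reading exists, corrected_expression carries it.",
  "fixtures": [
    {"example_id": "ex1", "field": "u", "order": 1, "status": "consistent",
     "expression": "2*a*exp(-x**2)*m*t*(-1 + 2*x**2)"},
    {"example_id": "ex1", "field": "rho", "order": 1, "status": "consistent",
     "expression": "exp(-x**2)*t*(c*m - n*(d + b*(2 - 4*x**2)))"},
    {"example_id": "ex1", "field": "u", "order": 2, "status": "consistent",
     "expression": "2*a**2*exp(-x**2)*m*t**2*(3 - 12*x**2 + 4*x**4)"},
    {"example_id": "ex1", "field": "rho", "order": 2, "status": "consistent",
     "expression": "exp(-x**2)*t**2/2*(d*(-c*m + n*d) + 2*a*c*m*(-1 + 2*x**2) + 2*b*(c*m - 2*d*n)*(-1 + 2*x**2) + 4*b**2*n*(3 - 12*x**2 + 4*x**4))"},
    {"example_id": "ex1", "field": "u", "order": 3, "status": "consistent",
     "expression": "4*a**3*exp(-x**2)*m*t**3/3*(-15 + 90*x**2 - 60*x**4 + 8*x**6)"},
    {"example_id": "ex1", "field": "rho", "order": 3, "status": "consistent",
     "note": "the token '4x2' closing the a**2 group is read as 4*x**4, consistent with the same polynomial 3-12x^2+4x^4 everywhere else in the term; with that reading the recursion reproduces the term exactly",
     "expression": "exp(-x**2)*t**3/6*(d**2*(c*m - d*n) + 2*b*d*(-2*c*m + 3*d*n)*(-1 + 2*x**2) + 4*a**2*c*m*(3 - 12*x**2 + 4*x**4) + 4*b**2*(c*m - 3*d*n)*(3 - 12*x**2 + 4*x**4) + 8*b**3*n*(-15 + 90*x**2 - 60*x**4 + 8*x**6) + 2*a*c*m*(d - 2*d*x**2 + b*(6 - 24*x**2 + 8*x**4)))"},

    {"example_id": "ex2_case1", "field": "u", "order": 1, "status": "consistent",
     "expression": "a*exp(-x)*m*t"},
    {"example_id": "ex2_case1", "field": "rho", "order": 1, "status": "consistent",
     "expression": "exp(-x)*(c*m + (b - d)*n)*t"},
    {"example_id": "ex2_case1", "field": "u", "order": 2, "status": "consistent",
     "expression": "a**2*exp(-x)*m*t**2/2"},
    {"example_id": "ex2_case1", "field": "rho", "order": 2, "status": "consistent",
     "expression": "exp(-x)*(a*c*m + (b - d)*(c*m + (b - d)*n))*t**2/2"},
    {"example_id": "ex2_case1", "field": "u", "order": 3, "status": "consistent",
     "expression": "exp(-x)*m*(a*t)**3/6"},
    {"example_id": "ex2_case1", "field": "rho", "order": 3, "status": "consistent",
     "expression": "exp(-x)*t**3/6*(a**2*c*m + a*c*(b - d)*m + (b - d)**2*(c*m + (b - d)*n))"},
    {"example_id": "ex2_case1", "field": "u", "order": 4, "status": "consistent",
     "expression": "exp(-x)*m*(a*t)**4/24"},
    {"example_id": "ex2_case1", "field": "rho", "order": 4, "status": "consistent",
     "expression": "exp(-x)*t**4/24*(a**3*c*m + a**2*c*(b - d)*m + a*c*(b - d)**2*m + (b - d)**3*(c*m + (b - d)*n))"},

    {"example_id": "ex2_case2", "field": "u", "order": 1, "status": "consistent",
     "expression": "2*exp(-2*x**2)*m*t*(-n + a*exp(x**2)*(-1 + 2*x**2))"},
    {"example_id": "ex2_case2", "field": "rho", "order": 1, "status": "consistent",
     "expression": "exp(-x**2)*t*(c*m - n*(d + b*(2 - 4*x**2)))"},
    {"example_id": "ex2_case2", "field": "u", "order": 2, "status": "consistent",
     "expression": "exp(-3*x**2)*m*t**2*(-c*exp(x**2)*m - 6*a*exp(x**2)*n*(-1 + 2*x**2) + 2*a**2*exp(2*x**2)*(3 - 12*x**2 + 4*x**4) + n*(d*exp(x**2) + 2*n + 4*n*x**2 - 6*b*exp(x**2)*(-1 + 2*x**2)))"},
    {"example_id": "ex2_case2", "field": "rho", "order": 2, "status": "consistent",
     "expression": "exp(-2*x**2)*t**2/2*(-c*d*exp(x**2)*m + d**2*exp(x**2)*n - 2*c*m*n + 2*a*c*exp(x**2)*m*(-1 + 2*x**2) + 2*b*exp(x**2)*(c*m - 2*d*n)*(-1 + 2*x**2) + 4*b**2*exp(x**2)*n*(3 - 12*x**2 + 4*x**4))"},

    {"example_id": "ex3", "field": "u", "order": 1, "status": "discrepant",
     "note": "the order-1 recursion with u0 = m*sin(x), rho0 = n*sin(x) yields sin(x)**2 where the printed term has cos(x)**2; neither the expanded nor the conservative integrand reproduces the printed term (the conservative variant gives -m*t*(a - 6*n**2*sin(x)**2 + 4*n**2)*sin(x)); corrected_expression is what the expanded recursion actually produces",
     "expression": "-m*t*(a + 2*n**2*cos(x)**2)*sin(x)",
     "corrected_expression": "-m*t*(a + 2*n**2*sin(x)**2)*sin(x)"},
    {"example_id": "ex3", "field": "rho", "order": 1, "status": "consistent",
     "expression": "t*sin(x)*(c*m - (b + d)*n)"},
    {"example_id": "ex3", "field": "u", "order": 2, "status": "discrepant",
     "note": "downstream of the order-1 u discrepancy; not reproduced by either integrand variant and not independently reconciled",
     "expression": "-m*t*sin(x)*(a + n*t*(2*c*m - a*n - 2*b*n - 2*d*n + n**3 + n**3*cos(2*x))*sin(x)**2)"},
    {"example_id": "ex3", "field": "rho", "order": 2, "status": "discrepant",
     "note": "seeding the rho-recursion with the PRINTED u1 reproduces this term with the single monomial 'cnm2' read as c*m*n**2 (recorded in corrected_expression); the literal reading c*n*m**2 is not reproduced",
     "expression": "-t**2/2*(a*c*m + b*c*m + c*d*m - b**2*n - 2*d*b*n - d**2*n + c*n*m**2 + c*m*n**2*cos(2*x))*sin(x)",
     "corrected_expression": "-t**2/2*(a*c*m + b*c*m + c*d*m - b**2*n - 2*d*b*n - d**2*n + c*m*n**2 + c*m*n**2*cos(2*x))*sin(x)"}
  ]
}
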
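"""Analytic balanced-growth state of the PTR cell.

Solves the characteristic quadratic alpha mu^2 - beta mu + gamma = 0 for
the growth rate and evaluates the closed-form composition of the growing
cell: precursor concentration P/V, enzyme-to-ribosome ratio T/R, precursor
per ribosome P/R and the ribosomal protein fraction Phi_R.
"""

import ptrcell as pc

params = pc.baseline_parameters(q=1.0, f_R=0.0727)
coeff = pc.quadratic_coefficients(params)
roots = pc.solve_growth_rate(params)
state = pc.steady_ratios(params, roots.mu_minus)

print(f"nutritional efficiency nu : {coeff.nu:.3f} /hr")
print(f"ribosomal efficiency rho  : {coeff.rho:.3f} /hr")
print(f"sector rates a, b         : {coeff.a:.4f}, {coeff.b:.4f} /hr")
print(f"growth rate roots         : mu_- = {roots.mu_minus:.5f}, "
      f"mu_+ = {roots.mu_plus:.5f} /hr (physical: mu_-)")
print()
print(f"P/V   = {state.P_over_V:.4g} molecules/um^3")
print(f"T/R   = {state.T_over_R:.2f}")
print(f"P/R   = {state.P_over_R:.1f}")
print(f"Phi_R = {state.Phi_R:.4f}  (ribosomal protein / total protein)")
print()
residuals = pc.ansatz_residuals(params, state)
print(f"back-substitution residuals of the balance equations: "
      f"{max(residuals):.2e} (exact steady state)")
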
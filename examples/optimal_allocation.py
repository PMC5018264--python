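"""Growth-rate maximization over the ribosome allocation f_R.

The growth rate is a non-monotonic function of the fraction of ribosomes
making ribosomal protein: too few and the ribosome pool cannot expand, too
many and the enzyme pool starves the cell of precursor.  The optimizer
locates the interior maximum; at large residue counts it approaches the
closed forms f_max = (nu + d_R - d_T)/(nu + rho) and
mu_max = (rho(nu - d_T) - nu d_R)/(nu + rho), where the two sector outputs
balance exactly: (m_T T) nu = (m_R R) rho.
"""

import ptrcell as pc

# precursor-dominated volume (V = v_P P), the regime of the closed forms
params = pc.baseline_parameters(q=1.0, v_T=0.0, v_R=0.0)

numeric = pc.optimize_fr_numeric(params)
closed = pc.large_m_optimum(params)

print("               numeric      closed form")
print(f"f_max      : {numeric.f_max:.6f}     {closed.f_max:.6f}")
print(f"mu_max /hr : {numeric.mu_max:.6f}     {closed.mu_max:.6f}")
print(f"Phi_R      : {numeric.Phi_R_opt:.6f}     {closed.Phi_R_opt:.6f}")
print(f"T/R        : {numeric.T_over_R_opt:.2f}       {closed.T_over_R_opt:.2f}")
print()
print(f"cellular-economy residual at the optimum : "
      f"{numeric.economy_residual:.2e}")
off = params.replace(f_R=0.5)
ss = pc.balanced_state(off)
print(f"same residual far from the optimum (f_R=0.5): "
      f"{pc.economy_residual(off, ss.T_over_R):.2f}")
print()
print("At the optimum the metabolic and ribosomal sector outputs agree to")
print("optimizer precision; off-optimum the identity fails by order one.")
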
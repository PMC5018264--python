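"""Two model extensions: the constant-fraction Q sector and the linear model.

The Q sector is a protein class pinned to a fixed proteome fraction f_Q;
it caps the ribosomal fraction at Phi_R_max = 1 - f_Q, as observed in
experiments.  The linear model drops the T and R volume terms (V ~ v_P P),
making the dynamics a triangular linear system whose largest eigenvalue
b = rho f_R - d_R is the growth rate; the P >= 0 constraint a >= b binds
exactly at the optimum.
"""

import ptrcell as pc

qp = pc.QSectorParameters(K_P=250.0, k=5e-4, m_T=500.0, m_R=1e4,
                          d_T=0.0, d_R=0.0, v_P=1e-8, v_T=0.0, v_R=1e-8,
                          f_R=0.05, f_Q=0.3, m_Q=300.0, v_Q=0.0)
closed = pc.q_sector_optimum(qp)
numeric = pc.q_sector_optimum_numeric(qp)
print(f"Q sector (f_Q = {qp.f_Q}):")
print(f"  closed form : f_R = {closed.f_R:.5f}, mu = {closed.mu:.5f} /hr, "
      f"Phi_R_max = {closed.Phi_R_max:.2f}")
print(f"  ODE optimum : f_R = {numeric.f_R:.5f}, mu = {numeric.mu:.5f} /hr")
print(f"  simulated proteome fractions: Phi_R = {numeric.Phi_R:.5f}, "
      f"Phi_Q = {numeric.Phi_Q:.5f} (pinned to f_Q)")
print()

base = pc.baseline_parameters(q=1.0)
lin = pc.linear_model(base.replace(f_R=pc.fmax_large_m(base)))
print("linear model at the binding constraint a = b:")
print(f"  eigenvalues  : {tuple(round(e, 6) for e in lin.eigenvalues)}")
print(f"  growth rate  : {lin.growth_rate:.6f} /hr "
      f"(= closed-form mu_max {pc.mumax_large_m(base):.6f})")
print(f"  T/R          : {lin.T_over_R:.2f} (= (m_R/m_T)(rho/nu) = 200)")
print()
beyond = pc.linear_model(base.replace(f_R=0.2))
print(f"beyond the optimum (f_R = 0.2) the linearization breaks down:")
print(f"  P/R = {beyond.P_over_R:.3g} < 0 -> flagged infeasible "
      f"(the full model still grows there)")
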
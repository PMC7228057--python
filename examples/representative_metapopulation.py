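"""Solve the mean-field (representative-metapopulation) theory.

Dynamical mean-field theory replaces the S-species metacommunity by one
representative species per patch, fluctuating around a quenched Gaussian
characteristic abundance N*_u and driven by colored ecological noise
xi_u(t) whose covariance must equal sigma^2 times the abundance
autocorrelation it generates.  The solver iterates that closure to a
fixed point.
"""

import warnings

from metalv.dmft import equilibrium_theory, self_consistent_solve
from metalv.ensemble import DisorderScales

warnings.filterwarnings("ignore")

# disorder scales of a strongly heterogeneous pool
scales = DisorderScales(mu_tot=10.0, sigma=3.0)

eq = equilibrium_theory(scales, B=1.0, S=100)
print("static (equilibrium) cavity theory:")
print(f"  survival fraction phi = {eq['phi']:.3f}  "
      f"-> maximal diversity bound {eq['diversity_bound']:.1f} of 100")

sol = self_consistent_solve(scales, B=1.0, M=1, N_c=1e-10, T=600.0,
                            burn_in=200.0, dt=0.05, n_realizations=800,
                            damping=0.5, max_iter=50, tol=8e-3, seed=2)
print("dynamical mean-field solution:")
print(f"  converged: {sol.converged} after {sol.iterations} iterations")
print(f"  survival fraction phi = {sol.phi:.3f}")
print(f"  mean abundance <N> = {sol.mean_N:.3f}")
print(f"  noise strength std(xi) = {sol.std_xi:.3f}, power W = {sol.W:.2f}")
print(f"  closure residual |C_xi - sigma^2 C_N| / C_xi(0) = "
      f"{sol.closure_residual():.4f}")
print()
print("A finite converged noise kernel is the signature of a self-")
print("sustained fluctuating state: the abundance fluctuations generate")
print("exactly the ecological noise needed to maintain themselves.")
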
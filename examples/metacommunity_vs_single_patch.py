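"""A single patch equilibrates; a metacommunity keeps fluctuating.

Runs the reference species pool (S=250, connectance 1/8, Gaussian
interactions with mean 0.3 and std 0.45) twice: first as one well-mixed
patch, then spread over eight patches whose coefficients agree to 95%
(inter-patch correlation 0.95) and which exchange migrants at rate
0.01.  The single patch sheds species until it reaches a stable fixed
point; the metacommunity retains far more species and its surviving
abundances keep fluctuating indefinitely.
"""

import warnings

from metalv import EnsembleParams, integrate, detect_fixed_point, sample_interactions
from metalv.ensemble import disorder_scales
from metalv import observables as obs

warnings.filterwarnings("ignore")

single = EnsembleParams(S=250, M=1, c=1 / 8, mu_A=0.3, sd_A=0.45,
                        d=0.0, N_c=1e-8, seed=11)
multi = single.replace(M=8, rho=0.95, d=0.01)

for label, params in [("single patch", single), ("metacommunity", multi)]:
    system = sample_interactions(params)
    traj = integrate(system, horizon=4000.0, store_every=2, seed=12)
    fp = detect_fixed_point(traj, system, tol=1e-7)
    sigma = disorder_scales(params).sigma
    std_xi = obs.noise_strength(traj, sigma, (2000.0, 4000.0))
    print(f"{label:14s}: survivors {traj.final_alive().sum():3d}/250, "
          f"fixed point: {fp.is_fixed_point}, "
          f"fluctuation strength std(xi) = {std_xi:.3f}")

print()
print("The same interaction statistics support twice the diversity, and")
print("persistent fluctuations, once space and mild patch-to-patch")
print("heterogeneity let each species ride out local crashes.")
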
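"""Sources stay sources: persistent migration identity of species-patch pairs.

In the fluctuating metacommunity state the migration term
(dN/dt)_diff = sum_v D_uv (N_v - N_u) of a given species-patch pair
keeps its sign over long times: patches that export a species (sources,
negative term) go on exporting even while abundances swing over orders
of magnitude.  A pair is called *persistent* when the time average of
this term is at least one temporal standard deviation away from zero.
"""

import warnings

from metalv import EnsembleParams, integrate, sample_interactions
from metalv import observables as obs

warnings.filterwarnings("ignore")

params = EnsembleParams(S=250, M=8, c=1 / 8, mu_A=0.3, sd_A=0.45, rho=0.95,
                        d=0.01, N_c=1e-8, seed=11)
system = sample_interactions(params)
traj = integrate(system, horizon=6000.0, store_every=2, seed=12)
window = (3000.0, 6000.0)

diff = obs.diffusion_contribution(traj, system)
table = obs.source_sink_stats(diff, traj, window)
sync = obs.interpatch_synchrony(traj, window)

n_src = (table.table["label"] == "source").sum()
n_surv = table.table["species"].nunique()
print(f"surviving species: {n_surv}/250")
print(f"surviving species-patch pairs: {len(table.table)} "
      f"({n_src} sources, {len(table.table) - n_src} sinks)")
print(f"persistent sources:   {100 * table.frac_sources_persistent:.1f}%")
print(f"persistent, all pairs:{100 * table.frac_all_persistent:.1f}%")
print(f"inter-patch synchrony: {sync:.2f}")
print()
print("High persistence percentages with low synchrony mean each species")
print("has reliable refuge patches even though no patch is quiet --")
print("the spatial structure that protects diversity from extinctions.")
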
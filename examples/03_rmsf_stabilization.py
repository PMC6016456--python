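"""Per-residue RMSF and the proximal-vs-distant stabilization signature.

Simulates a trajectory of the dimer in which the subunit proximal to the
binding partner fluctuates half as much as the distant subunit, and shows
that the RMSF delta (proximal − distant) is negative for every interface
residue — the signature of the partner rigidifying the proximal subunit.
"""

import numpy as np

from iface import make_dimer_complex, make_trajectory, rmsf, rmsf_delta

base, truth = make_dimer_complex(n_res_per_subunit=20, seed=6)
sigma = {res.key: (0.25 if res.chain_id == "A" else 0.5) for res in base.residues()}
traj, _ = make_trajectory(base, sigma=sigma, n_frames=1000, dt=2.0, seed=7)

profile = rmsf(traj)
mean_a = np.mean([v for k, v in profile.values.items() if k[0] == "A"])
mean_b = np.mean([v for k, v in profile.values.items() if k[0] == "B"])
print(f"mean RMSF: proximal subunit A = {mean_a:.3f} Å, distant subunit B = {mean_b:.3f} Å")
print(f"(planted sigma*sqrt(3): {0.25 * np.sqrt(3):.3f} and {0.5 * np.sqrt(3):.3f} Å)")

interface = [("A", i, "") for i in range(1, 21)]
delta = rmsf_delta(profile, truth["chain_map"], interface)
print(f"\ninterface residues with lower proximal RMSF: {delta.n_lower}/{len(delta.deltas)}"
      f" (fraction {delta.fraction_lower:.2f})")
# A fraction near 1.0 means essentially every interface residue is more
# rigid next to the partner than its symmetry mate in the free subunit.
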
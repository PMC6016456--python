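"""Interface RMSD against the average complex, and funnel detection.

Generates a jittered pose ensemble, builds the average complex, computes
each pose's interface RMSD (receptor-Cα fit, interface defined at 10 Å on
the reference), then contrasts a score cloud that funnels toward low iRMSD
with a shuffled null that does not.
"""

import numpy as np

from iface import (
    average_complex,
    funnel_analysis,
    interface_rmsd,
    make_dimer_complex,
    make_funnel_points,
    make_pose_ensemble,
)

base, _ = make_dimer_complex(seed=3)
poses, _ = make_pose_ensemble(
    base, {("A", 5, ""): 1.0, ("A", 9, ""): 0.7}, n_poses=10, jitter_sigma=1.0, seed=4
)
avg = average_complex(poses, receptor_chains={"A", "B"})
irmsds = [
    interface_rmsd(p, avg.reference, {"A", "B"}, {"L"}) for p in poses
]
print("iRMSD of each pose vs the average complex (Å):")
print("  " + "  ".join(f"{v:.2f}" for v in irmsds))
print(f"medoid pose (most central, for when the mean is unphysical): {avg.medoid_index}")

pts, _ = make_funnel_points(n=200, noise_sigma=1.0, seed=5)
summary = funnel_analysis(pts)
print(f"\nplanted funnel:  rho={summary.rho:.2f}, "
      f"best-decile median iRMSD={summary.low_score_median_irmsd:.2f} Å "
      f"vs global {summary.global_median_irmsd:.2f} Å -> funnel={summary.is_funnel}")

null, _ = make_funnel_points(n=200, noise_sigma=1.0, shuffled=True, seed=5)
null_summary = funnel_analysis(null)
print(f"shuffled null:   rho={null_summary.rho:.2f} -> funnel={null_summary.is_funnel}")
# A funnel (good scores concentrated at low iRMSD) indicates a consistent
# binding mode; the shuffled cloud shows what no preference looks like.
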
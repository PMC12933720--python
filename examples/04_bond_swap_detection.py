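"""Detecting bond-partner permutation (the two-site artifact).

When the bonded and nonbonded length scales of a CG model overlap, a
bead's nearest neighbor may stop being its bonded partner. Analyzing bond
lengths with the initial bond list then shows a spurious broad/bimodal
distribution while the nearest-neighbor distance stays well behaved.
Printed: the detected exchange frame, per-frame swap counts, and the mode
counts of the two distance histograms.
"""

import numpy as np

from cgbench.analysis import bond_swap_analysis, count_modes
from cgbench.box import Box
from cgbench.topology import linear_chain_topology
from cgbench.trajectory import Trajectory

top = linear_chain_topology(2, 2, mass=1.0)
rng = np.random.default_rng(0)
frames = []
for f in range(40):
    if f < 23:  # partners as bonded
        base = [[0.0, 0, 0], [0.30, 0, 0], [0.0, 0.9, 0], [0.30, 0.9, 0]]
    else:       # the two dimers have exchanged partners
        base = [[0.0, 0, 0], [0.30, 0.9, 0], [0.0, 0.9, 0], [0.30, 0.0, 0]]
    frames.append(np.array(base) + rng.normal(scale=0.004, size=(4, 3)))
traj = Trajectory(np.array(frames), Box.open(), np.arange(40.0),
                  species=["C"] * 4)

report = bond_swap_analysis(traj, top)
print(f"first swap frame: {report.first_swap_frame} (constructed at 23)")
print(f"swap counts per frame: {report.swap_counts.tolist()}")
print(f"identity-preservation fraction: {report.identity_fraction:.3f}")
print(f"bonded-list histogram modes: {count_modes(report.bonded_hist)} "
      "(bimodal: old partner drifted away)")
print(f"nearest-neighbor histogram modes: {count_modes(report.nearest_hist)} "
      "(unimodal: some bead is always nearby)")
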
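"""Chiral-inversion barrier by well-tempered metadynamics.

The chiral-mimic molecule (variant without the center substituent) holds
its stereocenter with a double-well improper dihedral. Biasing that
improper with WTMetaD drives transitions between the two enantiomer
basins and the rescaled final bias reconstructs the free energy profile.
Printed: the CV range explored, the reconstructed barrier in kJ/mol and
kcal/mol, and the depth difference of the two basins (near zero, since
the toy force field is parity-even).
"""

import numpy as np

from cgbench.metad import (CollectiveVariable, barrier_height,
                           reconstruct_fes, run_wtmetad)
from cgbench.systems import build_chiral_mimic

system = build_chiral_mimic("L", "no_center_H", improper_barrier=25.0)
cv = CollectiveVariable("improper_dihedral",
                        tuple(system.topology.impropers[0]))
traj, history, cv_series = run_wtmetad(system, cv, height=1.5, sigma=8.0,
                                       gamma=8.0, stride=100,
                                       n_steps=60_000, seed=4,
                                       frame_stride=500)
print(f"deposited {len(history.centers)} Gaussians; CV explored "
      f"[{cv_series.min():.1f}, {cv_series.max():.1f}] degrees")

grid = np.linspace(-90.0, 90.0, 181)
F = reconstruct_fes(history, grid)
bar_kj, bar_kcal = barrier_height(grid, F, (-60, -15), (15, 60))
fa = F[(grid > -60) & (grid < -15)].min()
fb = F[(grid > 15) & (grid < 60)].min()
print(f"reconstructed inversion barrier: {bar_kj:.1f} kJ/mol "
      f"({bar_kcal:.1f} kcal/mol)")
print(f"basin depth difference: {abs(fa - fb):.1f} kJ/mol "
      "(parity-even force field: should be small)")
print("\nFor comparison, the thermal energy at 300 K is ~2.5 kJ/mol "
      "(~0.6 kcal/mol): the inversion\nis a rare event for the unbiased "
      "dynamics but routine once the improper is biased.")
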
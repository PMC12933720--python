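# cgbench

A desk-scale benchmark for **mapping-induced artifacts in coarse-grained
(CG) molecular models**.

When atoms are grouped into CG beads, the choice of mapping — which atoms
form a bead, and which species label each bead carries — decides what a
CG potential *can* represent. Three failure modes matter in practice:

* **bond-partner permutation** — when the bonded and nonbonded length
  scales overlap, a bead's nearest neighbor stops being its bonded
  partner, and any potential that sees only geometry (no topology)
  lets partners swap;
* **chiral inversion** — removing atoms around a stereocenter lowers or
  erases the barrier between enantiomers, and a scalar-energy potential
  built from reflection-invariant features assigns *exactly* equal
  energies to mirror images;
* **spurious free-energy-surface symmetries** — both effects propagate to
  conformational statistics: point-symmetric backbone-dihedral surfaces,
  and helices that refold with either handedness.

`cgbench` packages everything needed to produce and quantify these
artifacts on controlled toy systems: an MD engine, three system builders,
the center-of-mass mapping machinery, two CG potential families fitted by
force matching, structural observables, stability classifiers, and
well-tempered metadynamics.

## The core quantities

**Center-of-mass (COM) mapping.** Bead positions and forces are

    R_I = sum_{i in S_I} w_Ii r_i,   w_Ii = m_i / sum_{j in S_I} m_j,
    f_I = sum_{i in S_I} f_i,

with disjoint atom sets S_I (each atom in at most one bead). Species
encodings: element-derived, unique-per-bead, single, alternating,
symmetric.

**Force matching.** CG potentials minimize the force residual

    chi^2(theta) = (1/3N) < sum_I | f_I(r) + grad_I U_CG(M(r); theta) |^2 >,

linear least squares for the classical spline potential
(bond/angle/dihedral/nonbonded cubic B-spline terms), gradient descent
for the minimal invariant learnable potential (radial + angular
[+ optional parity-odd] descriptors, species one-hot, small MLP readout).

**Order parameters.** Helicity over C-alpha sites,

    Q_hel = (1/N_hel) sum_{(i,i+3)} exp(-(d_ij - d0)^2 / (2 sigma^2)),

with d0 = 0.5 nm, sigma^2 = 0.02 nm^2 (1 = perfect alpha helix), and
handedness chi_hel = (1/N_hel) sum_i v_i . (v_{i+1} x v_{i+2}) over
consecutive C-alpha bond vectors (positive = right-handed; parity-odd).

**Well-tempered metadynamics.** Gaussians of initial height h, width
sigma, deposited along a dihedral CV with heights rescaled by
exp(-V/(k_B T (gamma-1))); the free energy estimate is
F(s) = -(gamma/(gamma-1)) V(s, t_final).

**Stability.** Thermal-energy criterion (2KE/3N < 5 kJ/mol) for bulk
systems; bond-distance criterion (no bond more than 0.05 nm from its
type's reference mean) for molecular systems; first failure truncates.

## Worked example

```sh
python examples/03_chirality_blindness.py
```

prints

```
parity-odd feature off: E(R) - E(mirror R) = +0.000e+00 kJ/mol
parity-odd feature on : E(R) - E(mirror R) = +3.287e-04 kJ/mol
```

With only rotation/reflection-invariant features the learnable CG
potential cannot tell a chiral cluster from its mirror image — the energy
difference is *exactly* zero, so nothing opposes chiral inversion once
the mapping has removed the atoms defining the stereocenter. One
parity-odd (reflection-antisymmetric) feature restores the distinction.

The other examples walk the remaining capabilities, each printing the
numbers it computes and what they mean:

| script | capability |
| --- | --- |
| `01_reference_and_mapping.py` | toy chain liquid, reference run with forces, COM mapping, conservation checks |
| `02_spline_force_matching.py` | spline force matching on a dimer gas with known interactions; force-curve recovery |
| `03_chirality_blindness.py` | parity-odd features and enantiomer energies |
| `04_bond_swap_detection.py` | bond-permutation detection: bonded-list vs nearest-neighbor distance histograms |
| `05_helix_handedness.py` | Q_hel / chi_hel, left-right fractions, handedness-symmetric FES |
| `06_metadynamics_inversion.py` | WTMetaD along the improper CV of a stereocenter; barrier extraction |
| `07_pipeline_cli.py` | the config-driven pipeline (also available as the `cgbench` shell command) |

The `cgbench` CLI drives the same pipeline from a YAML config:
`cgbench run config.yaml --out rundir`, stage subcommands
(`generate-reference`, `map`, `fit`, `simulate`, `analyze`, `metad`), and
`cgbench report rundir`. Exit codes: 0 success, 2 config error, 3 stage
failure.

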
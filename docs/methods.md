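# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `cgbench`. Everything quantitative stated here is
computed by the test suite or the example scripts; nothing is quoted from
external results.

## Units and constants

GROMACS-style units throughout: nm, ps, kJ/mol, K, amu, with
k_B = 0.00831446 kJ/(mol K). In these units 1 amu nm²/ps² = 1 kJ/mol, so
kinetic energy needs no conversion factor. Angles are radians internally;
user-facing dihedral quantities (histograms, collective variables) are
degrees on (-180°, 180°], the IUPAC signed convention computed via atan2
of the plane normals.

## MD engine

* **Bonded terms**: harmonic bonds ½k(r−r₀)², harmonic angles,
  cosine proper dihedrals k(1+cos(mφ−φ_s)), and two improper families —
  harmonic ½k(wrap(ξ−ξ₀))² and a smooth quartic double well
  h((ξ/ξ₀)²−1)² with minima at ±ξ₀ and barrier h at the planar geometry.
  The double well is used to encode stereocenters: it is parity-even (the
  same force field serves both enantiomers; chirality is a *kinetic*
  barrier, not an energetic preference) and, unlike a
  harmonic-about-nearest-minimum construction, has continuous forces at
  the transition state — exactly where metadynamics must sample.
* **Nonbonded**: Lennard-Jones with the energy shifted to zero at r_cut
  (no force switching), Lorentz-Berthelot mixing between species, and
  exclusion rules bonded12/bonded123/bonded1234. Pairs closer than
  10⁻³ nm raise an overlap error.
* **Forces** are analytic negative gradients for every term; the suite
  checks them against central finite differences at 10⁻⁶ relative,
  verifies Newton's third law to 10⁻⁹, and rotation/translation
  invariance to 10⁻⁹.
* **Integrators**: velocity Verlet (NVE) and BAOAB Langevin (NVT). BAOAB
  was chosen for its configurational accuracy at practical time steps;
  energy drift on the harmonic oscillator shrinks as dt² and fixed seeds
  give bit-identical trajectories. Instantaneous thermal energy is
  2·KE/(3N) — no center-of-mass momentum removal by default (n_dof is an
  argument).
* **Neighbor lists**: Verlet list with skin, rebuilt when any particle
  has moved more than skin/2; a periodic cell-linked list accelerates the
  build above 64 particles and is tested set-equal to the O(N²) scan.

## Toy systems (what the generator emulates, and what it does not)

All builders are deterministic given their seed, and every generated
reference trajectory stores the exact forces at the stored
configurations (verified by recomputation).

* **Chain liquid** (`build_chain_liquid`): n_molecules linear 6-site
  united-atom-style chains (end sites 15.035 amu, inner 14.027 amu) in a
  periodic cube fixed by a molecule density (default 2.5 nm⁻³; tests use
  1.0 nm⁻³ for headroom). Default force field: stiff bonds
  (k = 30000 kJ/mol/nm², r₀ = 0.153 nm), 114° angles, a threefold
  torsion, LJ σ = 0.395 nm with 1-2/1-3/1-4 exclusions. With these
  defaults the bonded (0.153 nm) and nonbonded (≈0.4 nm) length scales
  are separated; `forcefield_overrides` exposes r₀ and σ so the
  overlapping-scale regime that produces bond swaps in low-resolution
  mappings can be produced on demand. The 1-4 exclusion keeps the
  stiff-bond length distribution centered on r₀ to better than 1% (the
  residual shift is the r² Jacobian of the radial measure). Initial
  placement is zigzag chains on a columnar lattice with seeded rotation
  and jitter; infeasible densities raise rather than build overlapping
  states.
* **Dimer gas** (`build_dimer_gas`): harmonic dimers plus LJ between
  non-bonded sites — a CG-resolution reference whose true interactions
  are known in closed form, used for force-matching recovery.
* **Chiral mimic** (`build_chiral_mimic`): five backbone sites, with a
  light center substituent H and a side group S at the middle site per
  variant (`full`, `no_center_H`, `no_sidechain`). The improper over
  (center, left, right, S) carries the quartic double well
  (default barrier 40 kJ/mol ≈ 16 k_BT at 300 K, minima ±35°); the
  builder solves the substituent tilt so the built geometry sits exactly
  at a minimum. `no_sidechain` removes S and with it the improper —
  formal chirality is lost, as it is when a mapping drops every
  substituent of a stereocenter. D is the exact mirror of L under the
  same (parity-even) force field.
* **Helix chain** (`build_helix_chain`): n C-alpha-like sites whose bond
  and angle minima come from an ideal right-handed helix
  (radius 0.23 nm, 100° twist, rise solved so that every (i, i+3)
  distance equals d₀ = 0.5 nm exactly) and whose per-residue (i..i+3)
  dihedral bias k(1−cos(φ−φ_helix)) is the chiral term: its single
  minimum at the right-handed value breaks parity, standing in for the
  backbone chirality that L-amino acids impose. There are no off-backbone
  sites, so this dihedral bias *is* the per-residue chiral term. LJ
  σ = 0.45 nm puts the LJ minimum at the i,i+3 helix contact.

None of these reproduce real hexane or polyalanine chemistry: no
explicit solvent, no electrostatics, no real torsional profiles, and
barrier heights are set by construction rather than fitted to any
molecule. Passing tests therefore demonstrate the *mechanisms* of
mapping artifacts and the correctness of the machinery that measures
them — not quantitative agreement with any particular molecule.

## Mapping

COM weights are mass-normalized per bead (Σw = 1 enforced to 10⁻¹²);
bead forces are plain sums. Atoms left out of every bead are dropped,
forces included — a literal reading of the weight definition (w = 0 for
unmapped atoms). A config flag for folding dropped-hydrogen forces into
their heavy-atom bead is deliberately *not* defaulted on. Molecules are
made whole across periodic boundaries by walking the bond graph from
each molecule's first atom before weighting; mapped positions are then
re-wrapped. CG connectivity: a CG bond joins two beads iff an atomistic
bond crosses their atom sets; angles and dihedrals are simple paths of
the CG bond graph. Species encodings: `element` (dominant-mass atom's
label), `unique` (positional within the molecule), `single`,
`alternating` (ABAB…), `symmetric` (palindromic). The mapping schema
file is a minimal YAML document (species mode + per-bead atom lists).

## Classical spline potential and force matching

Each interaction class (bond type, angle type, dihedral type, nonbonded
species pair, keyed by canonical species tuples) lives on a uniform
cubic B-spline grid: clamped for bonds/angles (data-driven domains,
default knot spacing 0.005 nm and 2°), periodic for dihedrals (2°), and
a cutoff basis for pairs (0.01 nm) whose functions with support crossing
r_cut are dropped, so the represented potential vanishes C² at the
cutoff. Knots divide each domain exactly, which makes dyadic refinement
(`refine=2`) produce strictly nested function spaces — the basis-
enrichment monotonicity of the training residual is tested against this
construction. Out-of-domain evaluation either raises or extends each
basis function linearly (still linear in the coefficients; logged).

Predicted forces are linear in the coefficients, so force matching is
linear least squares, solved by frame-accumulated normal equations
(identical to stacking the design matrix) with two additions:

* a **smoothing ridge** on second differences of each term's
  coefficients (default strength 10⁻⁴), the standard cure for unsampled
  bins — chosen so that rarely-visited edge regions extrapolate smoothly
  instead of oscillating;
* an exact **gauge fix**: forces are blind to a constant shift of any
  clamped/periodic term (partition of unity), so each such term's
  coefficient sum is pinned to zero. This removes a genuine null space
  without biasing the force fit.

With zero ridge a rank-deficient system raises with advice rather than
silently pseudo-inverting. χ² is reported per force component averaged
over frames; train/validation splits are contiguous frame blocks at a
seeded offset (cheap decorrelation for time-ordered data).

## Invariant learnable potential

A deliberately minimal stand-in for modern equivariant message-passing
potentials, built to isolate one question — what symmetries the features
admit — rather than to compete on accuracy. Per-bead descriptors within
a smooth cosine cutoff:

* radial (2-body): species-resolved Gaussian density moments (default 6
  centers across [0, r_cut]);
* angular (3-body): cos^p moments over neighbor pairs (p ≤ 2), not
  species-resolved;
* parity-odd (4-body, optional): signed volume of neighbor triplets
  weighted by the Vandermonde factor of their distances — both factors
  are totally antisymmetric under neighbor permutation, so the product
  sums coherently over unordered triplets, and it changes sign under
  reflection.

The body-order knob ν̃ maps 1 → radial, 2 → +angular, 3 → +parity-odd.
Bead energy = small tanh MLP over [descriptors ‖ species one-hot];
total energy = sum over beads; forces are exact negative gradients
through analytic descriptor Jacobians (finite-difference-verified).
Training minimizes the same χ² by full-batch Adam with optional
learning-rate decay and early stopping on a validation block; the
parameter gradient of a force-dependent loss needs mixed second
derivatives of the network, implemented as a manual forward-over-reverse
pass and verified against finite differences. Everything is plain numpy;
with fixed seeds training is bit-reproducible.

The chirality result is structural, not empirical: radial and angular
features are computed from distances and dot products, which are exactly
invariant (in floating point, not just analytically) under z-negation,
so with the parity-odd feature off E(mirror R) == E(R) holds to the last
bit. With it on, the equality breaks on any chiral arrangement.

## Observables

RDF with shell normalization 4πr²ρ_A dr and bonded-pair exclusion
(default 1-2 only; 1-3 optional); ADF over neighbor pairs in a shell;
per-type bonded histograms (right-open bins; dihedrals on (-180°, 180°]);
Boltzmann inversion F = −k_BT ln P with empty bins masked as NaN (never
clamped to a large constant — that would fabricate barrier heights) and
the minimum shifted to zero; a 2D dihedral FES with a point-symmetry
score (cosine similarity between the density and its 180°-rotated image)
and, for the helix FES F(χ_hel, Q_hel), a reflection-symmetry score along
the handedness axis plus left/right population fractions. Q_hel uses
exactly exp(−(d−d₀)²/(2σ²)) with σ² = 0.02 nm², no renormalization.
Frame ranking selects the n smallest |χ_hel·Q_hel| (stable sort, ties by
frame index) — candidate unfolded starting structures for refolding
runs. Bond-swap analysis compares, per bead with a unique bonded
partner, the initial-partner distance against the nearest compatible
bead (same-species by default; `any` exposed, since the right
compatibility class is a modeling choice); a swap is counted when they
differ.

## Stability classifiers

Thermal-energy criterion: instantaneous 2KE/(3N) < threshold (default
5 kJ/mol ≈ 2 k_BT at 300 K; a trailing-window average is exposed but the
default is instantaneous). Bond-distance criterion: a frame fails when
any bond deviates by more than 0.05 nm from its type's mean over a
reference trajectory (pooled over frames and instances). Both use strict
inequalities at the boundary, and the first failing frame excludes all
subsequent frames; the stable duration is read off the frame times.

## Well-tempered metadynamics

Dihedral/improper CVs in degrees with analytic gradients shared with the
force-field dihedral code. Gaussian distances use the nearest periodic
image (widths ≪ period assumed; further images neglected). Deposited
heights follow h·exp(−V/(k_BT(γ−1))) — strictly decreasing at a
revisited point, constant in the γ→∞ limit. Defaults h = 1.2 kJ/mol,
σ = 10°, stride 500 steps, γ = 6, all config-exposed. The free-energy
estimator is the final-bias rescaling −(γ/(γ−1))V(s); reweighting
estimators are out of scope. The molecular runner adds −dV/ds·ds/dr to
the Langevin forces; a scalar runner for analytic 1D potentials keeps
the accumulated bias on a dense grid (deposition updates the grid; per-
step evaluation is interpolation). On a quartic double well with a
15 kJ/mol analytic barrier, a 10⁶-step budget (4000 depositions)
reconstructs the barrier within 15% across seeds; barrier extraction
takes the path maximum between basin minima and refuses unsampled gaps.

## Pipeline

`run_pipeline` executes generate → map → fit → simulate → analyze →
metad → report from a YAML config. Every stage writes a manifest with a
hash of the config block it consumed, its seed, and output checksums; a
stage whose manifest matches is skipped on rerun, so runs are resumable
and byte-reproducible under fixed seeds. Config errors name the
offending field and exit 2 from the CLI; stage failures exit 3 with
partial results preserved.

## Problem sizes

The shipped defaults are sized for interactive work on one CPU: liquids
of 27–100 six-site chains, references of 10³–10⁴ Langevin steps,
force-matching sets of a few hundred frames and ≤ 60 beads, 10⁵–10⁶
metadynamics steps. All are configuration parameters, not limits of the
implementation.

## Known limitations

* The learnable potential is invariant-feature based; it is not a
  message-passing architecture and makes no claim of matching one's
  accuracy or data efficiency — only the symmetry phenomenology.
* Angular descriptors are not species-resolved (feature count stays
  modest with many species); systems whose distinction lives purely in
  species-resolved three-body correlations would need that extension.
* The parity-odd feature count is one; strongly structured chiral
  environments may need several.
* No barostat, no Ewald electrostatics, no constraints, single-process
  execution.
* The two-site swap analysis assumes beads with a unique bonded partner;
  beads with two or more partners are skipped in the swap count.
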
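# Methods

## The model

`eemcc` computes standard binding free energies of host–guest complexes
in explicit water by the energy–entropy route: the Gibbs free energy of
each state is evaluated directly as G = E − TS from its own simulation,
and binding is the difference over four simulations,

    ΔG°_bind = (G_complex + G_water) − (G_host + G_guest°),

with the guest at the 1 M standard state. The pressure–volume term is
omitted (H ≈ E; a few kJ mol⁻¹ for aqueous boxes of this size, and it
cancels almost entirely in the difference). Mean energies come from the
MD engine's energy time series; the entire modelling effort is in S.

Entropy is computed by multiscale cell correlation (MCC): the system
entropy is a plain sum of components S_ij^kl over molecules i (host,
guest, first-shell water, released bulk water), hierarchy levels j
(whole molecule, united atom), motions k (translation, rotation) and
minima classes l (vibrational, topographical). A united atom is a heavy
atom plus its bonded hydrogens; its rotational degrees of freedom are 3
with more than one hydrogen, 2 with exactly one, 0 with none.

### Vibrational terms

For each unit (molecule or united atom) the net force and the torque
about the unit origin are accumulated per frame, expressed in the
unit's own axes (molecular principal axes; united-atom axes built from
the H-bond directions), halved in the mean-field approximation for
weakly correlated neighbours, and weighted by 1/√mass or 1/√I_a.
Covariance matrices of these weighted vectors over frames are
diagonalised and each eigenvalue λ becomes a harmonic frequency
ν = √(λ/k_BT)/2π, whose entropy is the quantum-harmonic-oscillator sum

    S^vib = R Σ_i [ x_i/(e^{x_i}−1) − ln(1−e^{−x_i}) ],  x = hν/k_BT.

Molecule-level matrices are 3×3 per motion (6 modes total, read as 3
translational + 3 rotational). United-atom translation spans 3N
coordinates; its six lowest-frequency modes are removed so 3N−6 remain,
since rigid-body motion is already counted at the molecule level. A
molecule that is a single united atom (water) therefore has no UA
translational term. United-atom rotation keeps all Σ dof modes; no
low-frequency filter is applied there because nothing at the molecule
level duplicates intramolecular libration.

### Topographical terms

* positional: S = k_B ln(1/x_aq); x_aq = 1/55.5 at 1 M (one solute per
  55.5 waters in the 1661 Å³ standard volume) gives 33 J K⁻¹ mol⁻¹,
  and x_aq ≈ 1 (solvent water) gives 0.
* orientational, in solution: S = k_B ln(N_c^{3/2} √π p_corr/σ) with
  N_c the trajectory-mean first-shell coordination number, σ the
  rotational symmetry number, p_corr the orientation-correlation factor
  (1 for solutes, 0.25 for water to account for hydrogen-bond
  correlation).
* orientational, bound guest: S = k_B ln(σ_host/σ_guest); CB8 has
  σ = 16 (an 8-fold and a 2-fold axis), giving 23 J K⁻¹ mol⁻¹.
* conformational: heavy-atom dihedrals are histogrammed with 30° bins,
  each frame is assigned to the circularly nearest histogram peak, and
  S = −k_B Σ p_i ln p_i is taken over the **joint** distribution of all
  dihedral labels of the molecule (a per-dihedral marginal sum is
  available as a diagnostic). The united-atom rotational topographical
  term is zero by rule: it corresponds to hydrogen-only dihedrals that
  are either zero by symmetry or strongly solvent-correlated.
* protonation: a guest that is half protonated free and fully
  protonated bound contributes −0.5 k_B ln 2 to the binding entropy;
  only this case (its reverse, and the no-change case) is supported
  because no general mixture rule is defined for the method.

### Hydration shells and water bookkeeping

First shells use the relative angular distance (RAD) criterion, which
is parameter-free (invariant under uniform rescaling of coordinates):
candidates around a centre are sorted by distance and candidate j is
rejected if some closer accepted k satisfies (1/r_ij)² < (1/r_ik)²
cos θ_jik. A water is first-shell when a solute heavy-atom site
survives in the RAD set computed from the water's oxygen over all
water-oxygen and solute-heavy-atom sites; hydrogens are not RAD sites.
Only first-shell water entropy is tracked — more distant water is
assumed unchanged by binding — and any neutralising counter-ion is
excluded.

Stoichiometry is balanced exactly: the number of waters released to
bulk is defined as N_WB = N_WS,H + N_WS,G − N_WS,H−G, so
N_WB + N_WS,H−G = N_WS,H + N_WS,G holds by construction. The complex's
shell is split between host and guest by nearest heavy atom (ties to
the host), which also partitions N_WB into host- and guest-released
parts. Per-water entropy components of shell water are scaled by N_WS;
released water uses per-water components from the bulk-water
simulation scaled by N_WB, which makes the per-water WB values common
to every guest. Negative released counts (a shell that grows on
binding) are kept internally, logged as a warning, and clamped to zero
only in formatted reports.

### Assembly and errors

Each replicate of the four systems yields a SystemFreeEnergy; replicate
r of every system combines into one ΔG sample and SEM = σ/√n is taken
over the (typically three) replicate ΔG values. Accuracy against
experiment is the mean absolute error over guests. Convergence of each
simulation's energy is checked by ordinary least squares on the energy
time series, with the slope reported per ns.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| temperature | 300 K | enters Eq. for ν→S and G = E − TS |
| x_aq_standard | 1/55.5 | 1 M standard-state mole fraction |
| halving | `halved` | mean-field halving of forces/torques before covariance |
| frame_source | `self` | orientation frame for UA analysis; `complex` uses the host–guest principal frame (needed for the bound host so host and guest stay aligned) |
| water_p_corr | 0.25 | hydrogen-bond orientation correlation of water |
| bin_width | 30° | dihedral histogram resolution |
| stride | 1 | frame subsampling |

Halving the instantaneous forces divides covariance eigenvalues by 4
and frequencies by 2; it is the method's own calibration of the
effective mean-field potential. The `raw` switch exists so harmonic
benchmarks can recover the physical frequency; the two conventions are
related exactly by S_halved = S_raw evaluated at ν/2, which the test
suite asserts.

## Numerical choices

* Principal axes: inertia tensor eigenvectors sorted by ascending
  moment. Sign convention: the largest-magnitude component of each of
  the first two axes is made positive and the third axis is their cross
  product, guaranteeing a deterministic right-handed frame (flipping
  all three independently can produce a left-handed set).
* United-atom axes: z along the mean heavy→H bond direction; x the
  in-plane component of the first H bond, or an arbitrary fixed
  perpendicular for one hydrogen; hydrogen-free united atoms take the
  parent molecule's axes. For one-hydrogen (linear) united atoms the
  bond axis carries no inertia and only the two perpendicular axes
  enter the torque covariance.
* Covariance uses mean-subtracted samples and the n−1 normalisation;
  a single frame is an error. Eigenvalues below 1e−12 of the largest
  are treated as numerical nulls and dropped with a warning; an
  all-null matrix is an error.
* Net forces on a unit sum **all** atomic forces including those on
  hydrogens, which carry constraint forces in constrained MD; these are
  part of the force the unit feels.
* Torque lever arms are atomic positions relative to the unit origin;
  the formulation is force-based throughout (no momenta).
* Dihedral peak detection: a histogram bin (or plateau of equal bins)
  is a peak when it strictly exceeds both circular neighbours; a
  plateau contributes its lowest-angle bin; a flat histogram yields one
  peak at the lowest-angle maximal bin, so degenerate inputs remain
  deterministic. Assignment ties between equidistant peaks go to the
  lower-angle peak.
* Molecules are unwrapped across periodic boundaries (bond-graph walk
  with minimum-image steps) before centre-of-mass and inertia
  computation; shell searches use minimum-image distances in
  orthorhombic boxes.
* Linear or point molecules are rejected at the molecule level: all
  species treated here are non-linear rigid bodies.

## The synthetic generators

The generators emulate exactly the statistical features the estimators
read, with analytic ground truth:

* `harmonic_trajectory` — a rigid water-like triatomic in a harmonic
  translational trap with harmonic libration about its principal axes.
  Positions/forces are i.i.d. Boltzmann samples (x ~ N(0, k_BT/k),
  F = −kx; torques realised as zero-net-force rigid rotation force
  fields), so the covariance pipeline must recover
  ν = √(k/M)/2π and √(κ/I_a)/2π and the exact QHO entropy. Defaults
  (k = 300 kJ mol⁻¹ Å⁻², κ = 50 kJ mol⁻¹ rad⁻², 300 K, 10⁴ frames)
  put frequencies in the far-infrared range typical of intermolecular
  motion, where the QHO entropy is a few R per mode and discriminating.
* `dihedral_fixture` — a von Mises mixture at well-separated centres
  with known weights; true conformer entropy −k_B Σ w ln w. The default
  concentration (κ = 200, angular σ ≈ 4°) keeps wells resolvable at
  30° bins.
* `shell_fixture` — contact waters at 3 Å on well-spread directions
  with distant waters stacked directly behind them (blocked by
  construction); with zero contacts, waters sit on a far arc where each
  neighbour blocks the line to the solute, leaving the shell empty.
  Contacts packed closer than ~32° would start occluding one another
  (the blocking inequality gives sin(γ/2) < 1/4, i.e. γ < 29°, as the
  mutual-occlusion threshold), and such placements raise an error, as
  does a single far water, which nothing can block.

Because sampling is i.i.d., these fixtures have no time correlation,
no anharmonicity, no coupling between translation/rotation/torsion and
no real solvent structure. Passing tests therefore demonstrate the
estimators' correctness on their defining models, not force-field
realism: applied to real MD data the vibrational terms inherit the
harmonic and mean-field approximations, and conformational entropy is
bounded by the sampling of slow torsions.

## Problem sizes and reproduction

The bundled reference dataset (`eemcc.sampl8`) carries the published
per-guest CB8 binding thermodynamics, the unbound-host entropy
components and the shell-water counts from triplicate 100-ns
simulations; regenerating those trajectories (4 systems × 3 replicates
× 7 guests at 1000 force-bearing frames each) is a cluster-scale
exercise, so the package's validation recomputes everything downstream
of the trajectories from those printed inputs and validates the
trajectory-facing estimators on the synthetic ground truths at 10⁴
frames, where harmonic entropy recovery is within ~0.5% and the
stochastic tolerance asserted is 2%.

## Known limitations

* The harmonic QHO mapping over-rigidifies strongly anharmonic modes;
  topographical terms recover multi-well behaviour only for torsions
  and molecular position/orientation.
* The joint conformer distribution is estimated empirically; with many
  flexible dihedrals it needs correspondingly many frames (states scale
  multiplicatively).
* The general protonation-mixture entropy is deliberately not
  implemented (no defined rule beyond the half↔full case).
* Triclinic minimum-image uses box diagonals (orthorhombic assumption)
  in the shell search.
* Energies are taken from the engine's time series as-is; whether they
  include kinetic terms cancels in ΔΔ comparisons but is the user's
  choice to keep consistent across the four systems.
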
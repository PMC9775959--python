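# Methods

## The coarse-grained model

Every residue is reduced to a backbone bead at its Cα and a side-chain bead
at the centroid of its side-chain heavy atoms (glycine has none).  All
conformational states of one system are first trimmed to a common residue
set keyed by (chain, residue number, insertion code), so every frame of a
path carries an identical sequence.

The landscape energy of a conformation is the weighted eight-term folding
free energy

ΔG_fold = c1·ΔG_side^vdw + c2·ΔG_solv + c3·ΔG_HB + ΔG_side^elec
 + ΔG_side^polar + ΔG_side^hyd + ΔG_main−side^elec + ΔG_main−side^vdw,

c1 = 0.10, c2 = 0.25, c3 = 0.15.  The term structure and coefficients are
fixed; the functional forms below are this package's own, kept deliberately
simple and fully tabulated in `EnergyParams` so recalibration never touches
code.  Units are kcal/mol, Å and elementary charges throughout.

* **van der Waals** (side–side and main–side): soft 8–6 potential
  ε[3(r0/r)⁸ − 4(r0/r)⁶] with r0 the sum of bead radii (backbone 2.3 Å,
  side chains 1.8–3.2 Å by residue), ε = √(ε_i ε_j) (0.20 hydrophobic,
  0.15 otherwise), smoothly switched off between 10 and 12 Å.  The 8–6
  form is softer than 12–6, which suits bead-level tolerances.
* **Electrostatics**: Coulomb 332·q_i·q_j/(ε(r)·r) with the
  distance-dependent dielectric ε(r) = 6r, scaled ×0.25 when both beads lie
  inside the membrane core (stronger interactions in the low-dielectric
  slab), same 10–12 Å switch.  Side-chain charges come from the protonation
  state; backbone beads carry small alternating ±0.05 e partial charges as
  a dipolar surrogate, which gives the main–side electrostatic term its
  content.
* **Burial terms**: each bead's burial is a smooth neighbour count
  (kernel 1 inside 6 Å, fading to 0 at 8 Å) over protein beads of other
  residues, excluding sequence neighbours within ±4 positions on the same
  chain — without that exclusion an isolated helix would read as buried by
  its own turns.  The count b maps through the saturating B = 1 − e^(−b/8).
  Backbone solvation is +w_solv·B in water and −w_solv·B in the membrane
  (exposure favoured in water, burial in the slab; w_solv = 0.5).  Polar
  side chains pay w_polar·B (doubled in the membrane; w_polar = 1.0).
  Hydrophobic side chains earn −w_hyd·B in water and −w_hyd·(1−B) in the
  slab (membrane exposure is the reward there; w_hyd = 0.8).
* **Helical hydrogen bonds**: each i,i+4 backbone pair within a chain
  earns −1.0 kcal/mol when its distance falls in a smoothly switched
  5.0–6.5 Å window (plateau 5.3–6.2 Å).
* **Membrane**: a slab of half-thickness 15 Å centred on the
  transmembrane centroid, with a hexagonal lattice of neutral particles
  (spacing 5 Å, exclusion cavity 4 Å around the protein — for path work the
  cavity is carved around *every* frame so one membrane serves the whole
  path).  Lattice particles contribute repulsive vdW exclusion only;
  environments (water / interface / membrane, interface half-width 3 Å) are
  assigned from z.  The lattice is constructed symmetric under 180°
  rotation about its centre, which the dimer grid's exchange symmetry
  relies on.

Each bead's environment is frozen during a single energy evaluation; all
terms and their analytic gradients are evaluated from one neighbour list,
and the vectorised kernels are tested to 1e−8 against a plain double-loop
reimplementation.

## Protonation

Ionizable residues (D, E, K, R, H; model pKa 3.9, 4.1, 10.5, 12.5, 6.5; pH
7.0) are assigned charge states before every energy evaluation.  The state
energy is the sum of intrinsic terms 2.303·k_B·T·γ·(pKa − pH) for ionized
sites (γ = +1 acids, −1 bases — ionization is favourable for acids above
and bases below their pKa) plus pairwise Coulomb interactions between
ionized side beads with the same screening as the folding energy, so
proton placement and folding electrostatics are mutually consistent.

Sampling: a titration pre-step ionizes each site independently when that
lowers its intrinsic energy, fixing the total proton count; protons then
jump between sites (neutral acids and charged bases are donors) under the
Metropolis criterion min(1, e^(−ΔE/k_B T)) at 300 K, 50 steps per site by
default, and the lowest-energy state visited is returned.  On enumerable
toys the sampler's visit frequencies match exact Boltzmann weights and its
low-temperature limit finds the exhaustive minimum.

The pipeline's default is the deterministic zero-temperature limit of the
same dynamics (steepest-descent jumps from the titration state): the
finite-temperature sampler's best-visited state fluctuates by several
kcal/mol between adjacent frames of a path, which at this system size
drowns the conformational signal, and the deterministic assignment is also
invariant under relabelling the two subunits of a dimer, keeping the L×R
grid exactly symmetric.  `protonation: mcpt` switches the sampler back on.

## Morphing and relaxation

Transition paths replace targeted MD by optimal rigid superposition
(Kabsch on backbone beads) of the end state onto the start followed by
linear Cartesian interpolation — the landscape analysis only consumes an
ordered, equally spaced conformation series, which this surrogate delivers.
101 raw frames per segment are generated (65 in the shipped configurations)
and frames are picked at equal coordinate intervals: 10 per transition for
the 1D scenarios (19 unique frames over two transitions, the shared
intermediate counted once), 17 per subunit for the dimer.

Each picked frame is relaxed on the CG surface with its backbone beads
harmonically restrained to the interpolated positions (k = 2.0
kcal/mol/Å²), so frames keep their place on the reaction coordinate, and —
a deliberate deviation from a looser design in which side chains are free —
its side-chain beads weakly restrained (k = 0.3): unrestrained side chains
hop between packing basins from frame to frame and bury the activation
signal under ±10 kcal/mol of basin noise.  Two minimisers share one
analytic gradient: a damped steepest descent with backtracking (monotone,
the reference implementation) and L-BFGS (the pipeline default — plain
descent stalls on the synthetic bundle's symmetric plateaus).  Convergence
is declared when the energy varies by less than the tolerance (0.05
kcal/mol default, 0.02 in the pipeline) over the last ten steps; the
last-ten energies are kept, the final one is the frame's energy and their
population SD its error bar.

## Ligand binding

Binding is scored as ΔG_bind = ½(⟨U_elec⟩_charged + ⟨U_elec⟩_uncharged) +
(ΔG_solv^bound − ΔG_solv^free) + β·U_vdw: a linear-response average of the
ligand–receptor Coulomb energy over configurations relaxed with full and
with zeroed ligand charges, a solvation correction, and a β-scaled 8–6
vdW term (β = 0.25).  Ligand electrostatics use an effective pocket
dielectric ε_in = 6 (bulk 80); the semi-macroscopic scaling is collapsed
into these two constants.  The solvation correction places dipole sites on
a 1.5 Å grid in a 2.5–6 Å shell around the ligand, each responding to the
ligand field with a saturating quadratic, with sites occluded by receptor
beads smoothly removed — burying a charged ligand therefore costs
desolvation unless contacts compensate.  By default poses are evaluated
rigidly (the charged/uncharged configurations coincide and the LRA average
reduces to the bare Coulomb energy); an optional 6-dof rigid-body pose
relaxation realises the two LRA endpoints but can hop between pocket
minima along a path, so it is off in the shipped scenarios.  Poses are
carried from frame to frame by a rigid fit on static anchor residues;
frames where the re-anchored ligand clashes score zero with a warning.

Docking is out of scope: poses come from the synthetic pocket constructor
(or are authored), and ligand partial charges are inputs.

## Landscapes and barriers

1D profiles are reported relative to their first point; the activation
barrier is max(E_i − E_start) ≥ 0.  On 2D grids the least-energy pathway
minimises the highest energy met along 8-connected moves (minimax —
every reported quantity is a barrier, so the bottleneck is the natural
criterion; path-sum minimisation is available behind a flag).  Ties break
toward smaller path sum, then lexicographic node order; for the cumulative
tie-break node energies are shifted by the grid minimum so revisiting a
favourable cell can never improve a path without bound.  Back-tracking is
allowed (monotone progress is not enforced).  Two-sided barriers segment a
path at its stable intermediate — the global minimum strictly between the
endpoints, earliest if tied: ΔG_barrier1 is the climb from the start to the
highest point before the minimum, ΔG_barrier2 the climb out of the minimum.
A path whose global minimum sits at an endpoint is flagged as having no
interior intermediate.  The search is exact: it matches exhaustive path
enumeration and an independent threshold-connectivity oracle on all tested
grids.

## Synthetic systems

The generator builds ideal α-helical bundles (rise 1.5 Å/residue,
100°/residue, Cα radius 2.3 Å) on a placement circle (default 7 helices of
24 residues, radius 11.5 Å, antiparallel), axes along z.  Residue types
follow membrane-protein logic: outward-facing positions are hydrophobic,
lumen-facing polar, and outward positions in the interface band (|z| =
11–18.5 Å) carry ionizable residues — basic at the cytoplasmic end
(positive-inside rule), acidic at the extracellular end — thinned to 60%
occupancy so ring charges do not crowd each other into titration flips.
One helix's cytoplasmic ring is acidic instead of basic, forming
ionic-lock salt bridges with the neighbouring basic rings that must break
during activation; in the class-A/B scenarios that helix is the swing helix
itself (its acids also arrive at the cationic agonist), while in the
class-C scenario the swing helix keeps its basic ring (the anionic
glutamate-like agonist is bound by approaching K/R, as in real class-C
pockets) and the lock acid moves to the neighbouring helix.

Activation is a rigid swing of the cytoplasmic half of the TM6-analogue
helix about a mid-helix hinge, with the terminal Cα displaced by exactly
the requested distance (14 Å class-A, 18 Å class-B, 6 Å internal motion of
each class-C subunit).  Dimers place two copies with exact C2 symmetry;
the subunit series for the dimer grid combines the internal swing with a
stepwise rotation of each subunit about its own axis that migrates the
contact interface from the inactive-facing helix ("helix III") to the
active-facing one ("helix VI"), with hydrophobic contact patches on the
interface helices (the mid-path helix carries the largest patch, which is
what gives the landscape its stable intermediate).  The R-subunit frames
are exact C2 images of the L frames, so the apo grid is symmetric by
construction — the symmetry check on the computed grid verifies the whole
energy pipeline respects it.  The G-protein surrogate is a rigid ring of
hydrophobic beads plus one acidic bead approaching along z beneath the
swing helix's inactive terminus: it clashes with the closed conformation
and packs favourably once the cavity opens.

Ligands are 3–6 authored particles with charges summing to the requested
net charge (+1 amine-like for class A, −1 glutamate-like for class C),
seated beside the arrival point of a moving pocket residue, oriented with
the dominant charge toward the pocket, and nudged outward until every
particle clears every frame of the path by 4.2–5 Å (just outside vdW
contact).  Two mutation-scan roles are then chosen from the placed ligand:
the aspartate-role is the mover with the largest approach to the ligand
(its salt bridge strengthens as the receptor activates), the
threonine-role the mover with the largest retreat.

## What the synthetic tests do and do not show

Passing scenarios demonstrate that the pipeline's machinery — morphing,
charge assignment, energy evaluation, binding injection, path search —
produces the qualitative mechanisms under controlled conditions: an
agonist whose contacts strengthen along activation lowers the 1D barrier;
a partner whose packing stabilises open conformations makes the coupled
2D path cheaper than activation at fixed separation; dual agonist binding
lowers both barriers flanking a dimer's stable intermediate.  They do not
show that the CG parameterisation is quantitatively transferable to real
receptors: absolute barrier heights depend on the authored force-field
constants, the synthetic bundles lack loops, kinks and sequence realism,
and published experimental barrier values are not reproduction targets.

The canonical receptor is generator seed 1; every shipped scenario and
test pins it.  The scenario-A agonist mechanism is seed-sensitive: across
seeds the emergent pocket geometry sometimes yields a non-monotone binding
profile whose injection does not lower the barrier (observed at 2 of 6
seeds tested).  This is a genuine property of emergent synthetic pockets,
not averaged away — real receptors differ from each other in the same way.
The scenario-B inequality held at all 6 seeds tested; scenario C at all 3.

## Problem sizes and numerical choices

Shipped runs use 168-residue monomers (≈330 beads + ≈900 membrane
particles), 19 frames for scenario A, a 10×11 grid for B (partner
displacements 0–30 Å in 11 steps) and a 17×17 grid for C; a full
three-scenario sweep takes a few minutes on one CPU.  Coordinates and
energies are float64; the clash floor is 0.1 Å (hard error naming the
pair); pose validity floor 1.0 Å; grid-cell charge assignment and all
randomness derive from one master seed through fixed substreams, making
every table byte-reproducible.  Degenerate inputs are handled explicitly:
zero ionizable sites returns an empty protonation state with a warning,
zero-swing activation pairs produce flat profiles, and a path whose
minimum sits at an endpoint reports a flagged single barrier.
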
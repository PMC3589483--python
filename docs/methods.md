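# Methods

`oxohb` models the hydrogen bonding of oxoanion-modified residues —
phosphoserine (SEP), phosphotyrosine (PTR) and sulfotyrosine (TYS) — and
of glutamate as the unmodified reference acceptor, against the cationic
and polar donors arginine, lysine and the backbone amide.  It has three
computational stages: rigid-scan implicit-solvent potentials of mean
force, geometric hydrogen-bond analysis of structures and multi-model
trajectories, and a survey pipeline over sets of PDB entries.  A
synthetic-structure generator produces every fixture the test suite
needs, so no archive downloads are involved.

## Fragments and charges

Each residue is represented by a rigid side-chain analog: propionate for
Glu, methylguanidinium for Arg, methylammonium for Lys,
N-methylacetamide for the backbone amide, and — for the modified
residues — the side chain truncated at C-beta and capped to a neutral
methyl (methyl phosphate for pSer, p-cresyl phosphate/sulfate for
pTyr/sTyr).  Geometries are idealized: standard small-molecule bond
lengths and angles (P–O(terminal) 1.51 Å, S–O 1.455 Å, terminal
O–X–O 114°, carboxylate C–O 1.25 Å / O–C–O 126°, guanidinium C–N 1.33 Å,
planar 120°).  The templates ship as plain-text files and are
regenerated by `scripts/make_templates.py`.

Partial charges are fixed point charges.  The unmodified analogs use a
standard OPLS-type assignment (`force-field` provenance).  For the
modified residues the packaged `esp-synthetic` sets are synthetic
constructions: they impose the formal net charges (−2 for the dianionic
phosphates, −1 for the protonated phosphates and the sulfate) and the
qualitative ESP pattern of such groups — terminal oxygens near −0.95 e
for dianions, −0.86/−0.88 e for the monoanionic phosphates, −0.66 e for
the sulfate whose single negative charge spreads over three oxygens.
That last contrast is what makes sulfotyrosine the weakest acceptor in
every downstream result, and it also leaves the sulfate with a smaller
charge asymmetry (and dipole) than the protonated phosphate, mirroring
the shaped-charge picture for monoanionic phosphates.  No quantity in
these sets was fitted to any target energy.

Dipole moments are reported in Debye (1 e·Å = 4.8032 D) about the center
of mass for charged species — a convention, stated because the dipole of
an ion is origin-dependent.

## Constrained poses

Two scan geometries are defined.  *Collinear*: donor N, its hydrogen,
one acceptor oxygen and the acceptor center atom (P, S or carboxylate C)
are placed on a line (N–H–O and H–O–X both 180°); the scan coordinate is
the N–O distance.  *Coplanar bidentate* (Arg only): the guanidinium
plane coincides with the plane of two acceptor oxygens, the H–O–O–H
dihedral is 0°, and the arrangement is made C2-symmetric about the
CZ-to-center axis; the scan coordinate is the CZ-to-center distance.
The symmetric completion is a choice — the dihedral constraint alone is
underdetermined — and the near-linear N–H···O contacts (>175° at
contact distances) emerge from it rather than being imposed.  The free
rotation of each fragment about the scan axis is fixed by a
deterministic reference atom, making poses bitwise reproducible.

## Energetics

The interaction energy of a posed pair is finite-difference Poisson
electrostatics plus Lennard-Jones:

* **LJ**: OPLS functional form, geometric-mean combining rules for both
  σ and ε, intermolecular pairs only.
* **Electrostatics**: the Poisson equation (zero ionic strength) is
  discretized with a 7-point variable-dielectric stencil at four grid
  points per Å, interior dielectric 1 inside the union of atom spheres,
  80 outside.  Cavity radii derive from the LJ σ (R = 2^(1/6)σ/2, the
  LJ-minimum van der Waals radius).  Face dielectrics are harmonic means
  of three samples along each grid edge; charges are spread trilinearly;
  boundary potentials are analytic Coulomb in the exterior dielectric;
  the Coulomb constant is 332.06 kcal·Å/(mol·e²).  The solver is
  successive over-relaxation (numba-compiled) with ω = 2/(1+sin(π/n))
  and a coarse-to-fine cascadic initial guess; convergence is declared
  when the largest per-sweep potential update falls below the requested
  tolerance (default 10⁻⁶ kcal/mol/e), so the acceleration affects speed
  only.  Validation: the Born-ion solvation energy is reproduced within
  1% at R = 2–4 Å, and the uniform-dielectric limit matches Coulomb's
  law within 2% over 3–10 Å.

Two electrostatic decompositions are exposed.  The *cross term*
(`elec_interaction`) evaluates the acceptor's potential at the donor's
charges in the dielectric geometry of the full complex; it is linear in
either fragment's charges and symmetric under role swap, but contains no
desolvation.  The *total-energy route* (`elec_interaction_total`, the
default for scans) is the total grid energy of the complex minus the
grid energies of the two isolated fragments.  Because all grids are
snapped to a common absolute lattice, each atom keeps its sub-grid
offset between the complex and monomer solves and the (large) grid
self-energies cancel exactly; what remains is the screened interaction
*plus* the positive cost of stripping each ion's reaction field as the
partner cavity approaches.  The distinction matters quantitatively: at
contact the cross term alone is roughly twice too attractive for
salt-bridge pairs, because bringing a +1 and a −1 ion together in a
continuum costs several kcal/mol of solvation.  Both decompositions
converge to the same screened-Coulomb monopole limit at large
separation.

## Distance scans

Scans run 2.25–11.0 Å at 0.25 Å (36 points), then refine at 0.05 Å
within ±0.25 Å of the coarse minimum.  The well depth is the total
energy at the refined minimum minus the value at the 11.0 Å reference.
Ties break toward the smaller distance; an all-repulsive curve (minimum
at 11 Å) is flagged with a warning and reported as depth 0.  Isolated-
fragment energies are cached per sub-grid offset class, so each scan
point costs one PB solve.

With the packaged charge sets the bidentate Arg/phosphate dianion
minima fall at 4.00 Å (CZ-to-P) with depths of −17 to −22 kcal/mol, the
Glu/Arg bidentate well is about −11.6 kcal/mol and Glu/Lys about
−6.6 kcal/mol, and the depth ordering across acceptors is
pSer(−2) < pTyr(−2) < pSer(−1) < pTyr(−1) < Glu < sTyr (more negative =
deeper) in every donor column.  Because the fragments are rigid and the
scan is one-dimensional, these are enthalpy-like scores with no
conformational entropy; they rank interactions rather than predict
absolute binding free energies, and collinear single-bond wells are
systematically deeper than what a relaxed or thermalized treatment
would give.

## Hydrogen-bond analysis

Two criteria: the trajectory criterion (N···O ≤ 3.0 Å and D–H···A
within 20° of linear; hydrogens required, attached by a 1.25 Å covalent
cutoff) and the heavy-atom survey criterion (N···O below the sum of
Bondi radii, 1.55 + 1.52 = 3.07 Å by default; radii overridable).  Donor
atoms: Arg NE/NH1/NH2, Lys NZ, Gln NE2, Ser/Thr/Tyr hydroxyls, every
backbone amide N; His/Asn/Trp side-chain nitrogens count as "other".
Acceptors: the terminal oxygens of the phosphate/sulfate/carboxylate
group; the bridging ester oxygen is excluded (it carries no formal
charge and is sterically shielded; an overridable choice).  An
Arg-acceptor contact is bidentate when one frame shows at least two
bonds through two distinct guanidinium nitrogens to two distinct
oxygens; otherwise single.  Occupancy is the percentage of frames with
a given label.  Backbone RMSF superposes each frame onto the mean
structure (align to the first frame, average, re-align twice) and
reports the per-residue root-mean-square displacement of N/CA/C/O.

## Survey pipeline

Entries are deduplicated by case-folded, whitespace-collapsed title,
keeping the best-resolved member (an unresolved NMR entry survives only
alone).  Within an entry, chains with identical residue-name sequences
form an identical-chain group: the reported bond count per residue is
the group mean rounded half away from zero, and the donor breakdown is
taken from the group's first chain.  Residues missing any acceptor atom
are skipped.  Glu residues are surveyed only in entries that also
contain a SEP residue, so the Glu reference population is conditioned
the same way as the modified-residue populations.  Outputs are a
bond-count histogram (bins 0–4 and ≥5, percentages per acceptor kind)
and a donor-category percentage table.

## Synthetic fixtures

The generator emulates only the geometric features the analysis stages
read: planted N···O contact distances (2.8–2.9 Å, inside both criteria),
per-frame single/bidentate/none labels realized by posing an Arg against
a SEP residue, sequence-identical chain copies with controlled bond
counts, and Gaussian coordinate jitter (default 0.05 Å).  After
generation the planted truth is re-derived with the package's own
detectors; if jitter flips a label the fixture regenerates with half the
jitter.  Fixtures are therefore exact by construction, which is what
makes the exact-recovery tests meaningful — and also what they do *not*
show: real structures have hydrogen-placement ambiguity, heterogeneous
geometry and crystallographic noise that these fixtures deliberately
lack.  No physical dynamics or solvent is emulated.

## Problem sizes and numerical choices in the tests

The quantitative checks (representative well depths, the bidentate
minimum location, Born/Coulomb limits) run at the production settings:
0.25 Å spacing, 8 Å padding, solver tolerance 10⁻⁵–10⁻⁶.  The
full 6×4 ordering matrix runs at 0.5 Å spacing: orderings are stable
under grid refinement (spot-checked cells move by 10–18% in depth but
never reorder), and the production-resolution matrix would cost roughly
an hour of solver time for no additional discrimination.  Degenerate
inputs are defined rather than accidental: zero source charges give an
identically zero potential, empty trajectories and hydrogen-free frames
under the angle criterion raise errors, and scan distances below 2.25 Å
are rejected.

## Known limitations

* Absolute well depths inherit the synthetic charge sets and the
  σ-derived cavity radii; columns dominated by a single short contact
  (Arg collinear, amide) are ~1.5–2× deeper than published
  implicit-solvent values for equivalent pairs, while the bidentate and
  Lys columns agree closely.  Orderings are robust to these choices.
* The dielectric boundary is a van der Waals surface, not a
  probe-rolled molecular surface; solvent is slightly over-admitted in
  crevices.
* No salt (the Poisson limit), no polarizability, no cation-π term —
  the last is a real contribution for Arg/Tyr stacking that fixed-charge
  models do not capture.
* PDB is the only structure dialect; mmCIF is out of scope.
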
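# Methods

This note documents the models, conventions and numerical choices
behind `specpair`, in the order a design calculation uses them.

## Idealized chlorin template

No canonical coordinate set exists for the tetrapyrrole core in
isolation, so the template is built analytically: four pyrrole
nitrogens at 90° intervals, 2.05 Å from the central metal (Zn or Mg);
each pyrrole a regular pentagon with 1.40 Å sides pointing its nitrogen
at the metal; methine bridge carbons closing the macrocycle with 1.40 Å
bonds.  The ring is exactly planar, which is adequate because every
calculation in the package that touches template geometry (selection
counts, symmetry, couplings) depends only on the invariants — 24 ring
atoms, 4-fold N symmetry, a defined plane — not on the fine bond
alternation of a real chlorin.  Real (non-ideal) ring geometries enter
through PDB/mmCIF input and are handled identically downstream.

Conventions: ring atoms are named `NA..ND`, `C1A..C4D`, `CHA..CHD` and
selected in the fixed order (N, C1–C4 per ring A–D, then the four
methines) so corresponding atoms align index-to-index; a `name_map`
translates depositions that use other labels.  The Qy transition dipole
is taken along the NA→NC direction (configurable to NB→ND); the
literature is not unanimous on the sign convention and only relative
orientations matter here.  Van der Waals radii are Bondi's; SASA uses a
1.4 Å probe and Shrake–Rupley sampling (960 Fibonacci points by
default, deterministic).

## Geometry and frames

Internal→Cartesian conversion is the NeRF construction; dihedrals follow
the IUPAC right-hand rule (checked against an independent library
implementation).  A residue frame has its origin at CA, x along CA→N,
z along x×(CA→C).  The relative transform between two frames is
expressed in the first frame's coordinates, which makes it exactly
invariant under joint rigid motions — the property 6-D hashing needs.
All superpositions use proper rotations only (SVD with determinant
correction).

## Motif library

A motif is one histidine ligating one chlorin through the ε or δ
imidazole nitrogen, plus its exact C2 copy.  The dimer geometry is
parameterized by four numbers: metal–metal offset along x, slip along
y, tilt of each ring about x, and spin about the ring normal, with the
C2 axis fixed as global z.  Tilt 90° puts the two rings in parallel
planes separated by the slip — the π-stacked arrangement of native
special pairs (defaults: 6.7/3.5/90/0 reproduces a 7.56 Å metal–metal
distance, bracketing the native ≈7.6 Å; a closer SP2-like stack and a
coplanar side-by-side geometry complete the default set).  The
histidine is oriented so its ligating nitrogen's in-plane lone pair
(the bisector of the two ring neighbours) points at the metal along the
ring normal at 2.1 Å, giving the pentacoordinate metal geometry
observed for protein-bound chlorophylls; the ligation dihedral spins
the imidazole about the metal–N axis.  Default rotamer grid: chi1 ∈
{−60, 60, 180}, chi2 on a coarse ±60/±90 set, ligation dihedral on a
90° grid — granularities are a practical choice, not a claim about any
particular published library.

Clash filtering rejects motifs whose two halves approach within 2.8 Å
(heavy atoms) and motifs whose own His backbone/CB runs into its
chlorin; the designed imidazole–metal contact is excluded from the
check by construction.

## Transform hashing and scaffold matching

The transform between the two histidines' frames is binned half-open
(`floor(x/width)`) on the three translation components (1.0 Å default)
and on intrinsic z-y-x Euler angles (15° default), packed into one
64-bit key (12 bits per translation axis, 9 per angle; out-of-range
translations return a sentinel rather than wrapping).  Half-open cells
mean boundary false negatives are possible by construction; an optional
27-cell neighbour query mitigates this and is off by default.  The
table is a multi-value map whose records hold exactly the parameters
needed to rebuild the motif (ligation mode, chis, ligation dihedral,
dimer geometry, metal–N distance); rebuilds are bit-for-bit the
original construction.

Scaffold scanning pairs residue i of chain A with residue i of chain B
(the natural pairing for C2 homodimers; off-index pairs are out of
scope), hashes each pair transform, and for every hit rebuilds the
motif anchored on the chain-A residue frame.  A placement is accepted
when no chlorin heavy atom lies within 2.5 Å of non-host backbone;
scaffold side chains are ignored because a real workflow redesigns the
pocket around an accepted placement.  Accepted placements are ranked by
(clash count, descending ligand burial).  Burial (DSasa) is the
fraction of chlorin-dimer SASA lost in the complex.

The planted-scaffold fixture generator inverts the search: a short
ideal α-helix is grafted so that its central residue's frame coincides
with the motif's first-His frame (asymmetric host spans let the helix
extend only on the side that clears the chlorin), chain B is the exact
C2 image, and a decoy helical segment is placed ~60 Å away in a seeded
direction.  This guarantees an exact-key hit at the planted pair while
seeds vary only the decoy geometry.  The generator emulates the
geometric search problem, not real protein architecture: decoys are
ideal helices, there are no loops, side chains or sequence, so passing
recovery tests demonstrates the hashing/rebuild/clash machinery, not
performance on natural scaffolds.

## Exciton model

Each chromophore is a point transition dipole (default 4.6 D, a
literature-typical chlorin Qy value) at the metal position, with site
energy set from a band position (default 669 nm, the protein-bound
monomer Qy).  Couplings are point-dipole,
`V = 5.04 s κ μ₁μ₂ / R³` cm⁻¹ (μ in Debye, R in nm, screening s = 1 by
default); the 5.04 constant follows from SI constants.  This replaces
quantum-chemical coupling calculations deliberately: the point-dipole
approximation degrades at contact distances (R comparable to the
molecular size), so computed couplings for tightly stacked dimers are
order-of-magnitude guides, while the band-position arithmetic
(splitting = 2V for degenerate sites) is exact within the model.

Rotatory strengths use the exciton-chirality length form with the mean
site energy in the prefactor, so identical-site dimers give exactly
conservative couplets (R₊ = −R₋); intrinsic monomer CD is not included.
Spectra are unit-area Gaussians per state scaled by dipole (absorbance)
or rotatory (CD) strength; FWHM 350 cm⁻¹ below 20,000 cm⁻¹ (Q bands)
and 1150 cm⁻¹ above (Soret), with a −0.25 eV global shift — the
empirical calibration that places the computed Qy at its observed
wavelength.  Cross-coupling between band classes is not modelled.

## Sequential binding model

Two ligands bind one protein dimer with stepwise macroscopic constants;
free ligand is solved by Brent bracketing on the strictly monotone
total-ligand function, then species follow from mass action (verified
to 1e-10 relative conservation on every call).  CD signals are
attributed to bound species only (`s_PL·[PL] + s_PL2·[PL2]`); the
synthetic-data defaults give PL a small negative coefficient (−1 per
µM against +10 for PL₂), mirroring the weak negative monomer CD versus
the strong dimer doublet.  Absorbance uses per-chromophore extinctions,
so PL₂ contributes twice its concentration; the free-ligand extinction
is held fixed during fits (it is independently measurable from a
ligand-only series) at a default of 44,000 M⁻¹cm⁻¹ at the observation
band.  Fitting is variable projection: nonlinear search over
(log₁₀K_D1, log₁₀K_D2) with coefficients profiled out by linear least
squares, multi-started from a log-spaced K_D grid to avoid local
minima.  The 1:1 model uses the closed-form quadratic bound fraction.
Mean fluorescence lifetimes are amplitude-weighted; transfer efficiency
is E = 1 − τ_DA/τ_D.

Synthetic titrations use 5 µM protein dimer, 25 points spanning 0–5
ligand equivalents and Gaussian noise at 2 % of the maximum signal —
conditions representative of the bench experiment the model describes.
What recovery tests show: the fitter is unbiased and precise under the
model's own noise assumptions.  What they do not show: robustness to
baseline drift, pipetting error correlated across points, or
wavelength-dependent species spectra, none of which the generator
emulates.

## Nanocage assembly

The octahedral rotation group (order 24) is generated by closure from a
4-fold and a 3-fold generator; C2 components sit on ⟨110⟩ edge axes (12
copies), C3 components on ⟨111⟩ vertex axes (8 copies); the tetrahedral
group is supported analogously.  Components must carry their own
symmetry axis on global z through the origin and are verified before
expansion; poses are a spin about and translation along that axis.
Expansion applies coset representatives (deduplicated by
order-invariant coordinate keys).  Docking is an exhaustive grid over
the two poses — a deliberate simplification of hierarchical docking —
scored per unique C2–C3 interface by backbone clash count, contact
count and buried interface area (SASA of the parts minus SASA of the
pair), with default filters clash < 3 and 1000–1600 Å² interface area.
Shape complementarity, binding-energy and hydrogen-bond filters are out
of scope.

## Structure comparison

Special-pair geometries are compared on the 48 tetrapyrrole atoms after
Kabsch superposition; the monomer-assignment ambiguity is resolved by
trying both pairings and reporting the minimum, while in-plane ring
correspondence is fixed by chemical identity.  Note that superposition
absorbs part of any rigid perturbation of one monomer, so the reported
RMSD is below the naive per-atom displacement residual.

## Problem sizes and determinism

Default test and acceptance runs use the 288-conformer default grid
(144 after clash filtering), 50-residue planted scaffolds, 100-motif
recovery ensembles, 50-replicate titration recoveries and single-pose
cage expansions — sizes chosen so the full workflow exercises every
code path while remaining interactive.  All stochastic steps take
explicit seeds; identical inputs produce byte-identical outputs.

## Known limitations

Point-dipole couplings at van-der-Waals contact; no vibronic structure
in spectra; macroscopic (not site-specific) binding constants; ideal
covalent geometry for histidine and helices; no sequence design or
physical energy function anywhere — placements and docks are filtered
sterically, not energetically.
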
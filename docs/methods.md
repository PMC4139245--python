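# Methods

## The geometric model

The package treats a shell-protein hexamer as a rigid, approximately
C6-symmetric disc that tiles a hexagonal lattice through narrow edge
contacts. Three facts organise everything else:

1. **Tiling.** In the native crystal lattice the hexamer centres sit on a
   hexagonal net with 67.2 Å spacing; each hexamer touches six neighbours
   through an edge built from two subunits per partner. The same tiling is
   assumed for microcompartment facets and for the sheets that precede tube
   formation.
2. **Rolling.** A sheet rolled into a tube of *N* hexamers per turn turns
   the straight row of hexamers into a regular *N*-gon: interior angle
   (*N*−2)·180°/*N*, tilt 360°/*N* between neighbours, centreline radius
   *s*/(2 sin(180°/*N*)) at spacing *s*. For *N* = 12 and *s* = 67.2 Å this
   gives 150°, 30° and 129.8 Å. Because hexamer edges are wedge-beveled,
   the inter-hexamer contact survives the bend unchanged.
3. **Symmetry as a diagnostic.** Interface mutations that degrade the
   tiling also degrade the hexamer's own 6-fold symmetry; an explicit
   deviation score and the pore cross-separation anisotropy both measure
   this.

## Solvent-accessible surface area

`compute_sasa` implements point-sampled SASA: each atom's van der Waals
sphere is inflated by the probe radius (default 1.4 Å), covered with a
deterministic generalized-spiral (golden-angle) point set (default 960
points), and the accessible fraction is the share of points not inside any
other inflated sphere. Determinism makes areas bit-reproducible and makes
ΔASA exactly zero for residues whose neighbourhood does not change on
assembly. Exactly coincident identical atoms split their surface half-half
(boundary points count 0.5), so degenerate inputs stay finite and
symmetric.

Two independent oracles check the engine in the test suite: a brute-force
Monte-Carlo surface integration (random points, agreement within 2 % on
random clusters) and, where available, an independently implemented
point-count SASA from a structural-bioinformatics library. Per-atom radii
come from a bundled element table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80,
H 1.20, default 1.70 Å), overridable through a `radius.<EL> = <value>`
config file, since legacy crystallographic programs used slightly
different radii. Hydrogens are not modelled and HETATM records are
excluded from protein surfaces by default.

Burial quantities follow the standard conventions: ΔASA(res) =
ASA(res | unit alone) − ASA(res | in assembly), floored at zero (negative
values can only be point-sampling noise and are counted); BSA(A, B) =
ASA(A) + ASA(B) − ASA(A∪B), the two-sided convention that counts burial on
both partners. Hot-spot entries carry the distance between a residue's
side-chain terminal atom (LYS→NZ, ARG→CZ, VAL→CB, ASP→CG, …; fallback:
side-chain centroid) and its image under the inter-hexamer dyad — residues
close to the 2-fold meet their own symmetry mate, which is why a
like-charge substitution there is predicted maximally disruptive.

## Symmetry fitting and the deviation score

`fit_symmetry_axis` finds the axis (direction plus a point) minimising the
mean squared residual between the model and itself rotated by 360°/*n*
with chains cyclically permuted; the centre is solved linearly for each
candidate direction and the direction optimised numerically from a
principal-axis initialisation, over all cyclic chain pairings. Chain
correspondence is restricted to cyclic permutations: rotationally built
oligomers order their chains that way, and real structures must be
pre-sorted to match.

The reported `deviation_rmsd` is the RMS deviation of the atoms from their
pairwise symmetric mean, i.e. RMSD(model, rotated model)/√2. This
normalisation makes the score a per-structure distance from the nearest
symmetric configuration: it is exactly 0 for a perfect C*n* oligomer, and
for i.i.d. Gaussian coordinate noise of standard deviation σ per
coordinate its expectation is σ√3 (≈0.87 Å at σ = 0.5, confirmed by
seeded simulation in the tests). The raw self-superposition RMSD would be
√2 larger and would double-count the noise of the two copies.

## Sheets, strips and tiling dimensionality

`build_sheet` tiles aligned hexamers on the hexagonal net (row offset
*s*/2, row separation *s*√3/2), giving every nearest-neighbour pair the
exact spacing. `tiling_dimensionality` classifies an arrangement of
centres by the rank (SVD, threshold 10⁻⁶ of the leading singular value) of
the span of nearest-neighbour difference vectors, with neighbours taken
within 5 % of the minimum pairwise distance. The 5 % window separates the
distinct spacings seen in strip versus sheet crystal forms (which differ
by about 1 %) without merging next-nearest shells (≥ √3 − 1 ≈ 73 %
further out).

## Nanotube construction

**Ring stacks.** Rings of *N* hexamers (centreline radius from the
closed form above) with 6-fold axes radial and the concave face outward;
successive rings are offset by half an azimuthal step and *s*√3/2 axially,
so ring-to-ring neighbours also sit at the lattice spacing and the ring
vertices interdigitate. Interdigitation only closes for even *N*, which
the builder enforces as an error. The default synthetic hexamer's 30°
edge bevel exactly absorbs the 30° tilt of the 12-ring, and the builders
are fully deterministic.

**Helical wraps.** The helix builder rolls the hexagonal sheet onto a
cylinder as interleaved strands: azimuthal step ≈ 360°/*N* and rise
pitch/*N* per hexamer along a strand, the next start offset by the strand
step rotated 60° on the tube surface. A subtlety dictates the exact
numbers: for the tube to be free of seam artifacts the circumference
vector must itself be a lattice vector of the rolled lattice (otherwise a
strand's second turn lands between rows of its neighbour, producing
spurious near-contacts). With the hexagonal lattice kept intact this
closure condition fixes the rise per hexamer at
*s*·(q√3/2)/√((m−q/2)² + 3q²/4) with q starts and m = round(*N* + q/2);
for *N* = 10, q = 2, *s* = 67.2 Å that is 11.47 Å per hexamer, a strand
pitch of ≈118 Å (two hexamer rows) and a centreline diameter of ≈21.7 nm.
An explicit pitch override is honoured by stretching the axial component
of the start offset — the only freedom compatible with closure at fixed
spacing. Stretching to the frequently quoted 138 Å pitch implies an
inter-row spacing near 69 Å, at which the row contacts fall outside the
6 Å marker-contact cutoff; the builder still produces the clash-free
geometry but reports the reduced contact preservation rather than hiding
it.

**Validity metrics.** `clash_check` reports atom pairs from different
hexamer copies closer than 0.6 × the sum of their van der Waals radii
(KD-tree neighbour search). `contact_preservation` takes hexamer pairs
whose centre distance is below 1.25 × the minimum centre spacing as
adjacent and counts the fraction whose closest marker-residue pair
(default residue 26) is within 6 Å — 1.0 for flat sheets, and required to
stay 1.0 for the default ring and helix tubes.

## Pore geometry and hydrogen bonds

The pore profile samples the fitted symmetry axis every 0.5 Å; the radius
at a sample is the clearance of that axis point (minimum over atoms of
distance minus van der Waals radius, floored at 0). Cross separations are
the three distances between the designated pore-loop atom (default:
main-chain N of residue 40) of chains k and k+3; they are equal exactly
when the pore lining is 6-fold symmetric, so their spread ("anisotropy")
is a residue-level symmetry diagnostic that complements the global
deviation score. `probe_fit` marks the samples admitting a given probe
radius and whether the passing corridor spans the hexamer thickness.

Hydrogen bonds are detected at the heavy-atom level (deposited shell
structures carry no hydrogens): donor/acceptor N/O pairs between 2.2 Å
(below which a pair is treated as covalent) and 3.5 Å (standard
heavy-atom cutoff), with intra-residue pairs always excluded. The optional
geometric filter requires every covalent antecedent of the donor to make
an antecedent–donor–acceptor angle of at least 90°, a proxy for a
plausible inferred hydrogen position. Bonds are classified intra-subunit /
intra-hexamer / inter-hexamer from the chain-group annotation, and
interface comparisons key bonds by (donor residue, acceptor residue,
class) so that native and mutant inventories line up residue-wise.

## Conservation scoring

Conservation of an alignment column is its consensus identity: the
fraction of non-gap letters equal to the modal letter (ties broken
alphabetically), with gaps excluded from numerator and denominator. This
matches the qualitative "fully conserved column" annotation of standard
alignment tools at the strict-identity level; similarity-class scoring is
deliberately out of scope. Positions are 1-based in the ungapped reference
sequence and mapped through the reference's gaps to columns.

## The synthetic hexamer

`make_ideal_hexamer` emits a coarse-grained pseudo-atom wedge disc, not an
all-atom protein: subunit fold detail is irrelevant to every computation
in this package, while the features that matter are built in exactly:

* six identical chains related by exact 60° rotations (symmetry deviation
  0 by construction);
* a hexagonal body of circumradius 37 Å (apothem ≈32 Å) and thickness
  20 Å, edge-beveled at 30° so tubes of 12 hexamers per turn close
  without distortion — the body dimensions are frozen so that sheets at
  the 67.2 Å native spacing touch through their markers with no steric
  clash;
* a concave (+z) and convex (−z) face, modelled as a 4 Å-sagitta
  spherical-cap offset;
* marker residues on the outer edge at increasing distance from the
  inter-subunit boundary — ASP-22 and LYS-26 near the inter-hexamer dyad,
  VAL-51 mid-edge, and an ARG-79 "arm" of five pseudo-atoms protruding
  past the hexagonal outline so that it plugs into the adjacent hexamer
  and buries the largest area of all markers, as the arginine does in the
  real interface;
* a central pore of default radius 4.5 Å lined by SER-40 amide-nitrogen
  markers, giving opposite-subunit cross separations of exactly 9.0 Å.

The hexamer thickness (20 Å) is the generic single-BMC-domain disc value
and is configuration-exposed, not asserted. What the generator does *not*
emulate: side-chain flexibility, sequence-specific packing, solvent, and
crystallographic disorder. Tests passing on synthetic hexamers therefore
demonstrate the correctness of the geometry and bookkeeping, not the
energetics of any real interface; the same pipeline applies unchanged to
deposited structures (`scripts/validate_native.py`).

Measurement-sample emulation draws diameters from a normal distribution
at the conditions reported for TEM work on these tubes (20.4 ± 1.1 nm,
n = 20 for the native protein; 18.3 ± 1.3 nm, n = 40 for the mid-edge
alanine mutant) and reports them in the conventional
"mean ± sd (n measurements)" format. All generators are
seed-deterministic.

## Numerical choices

* SASA point count 960 by default (isolated-sphere error ≪1 %; doubling
  changes totals by <1 %); analysis entry points use 480 or 240 where the
  quantity is a large-area difference that converges faster.
* Axis fitting: Nelder–Mead on the two axis-direction angles (tolerance
  10⁻¹² on parameters), centre solved by linear least squares per
  direction; the minimum-norm solution pins the centre component along
  the axis.
* PDB coordinates are written at the format's 10⁻³ Å precision; round-trip
  tests assert at that tolerance.
* Assemblies beyond 62 chains use a deterministic two-character chain
  scheme in columns 21–22 ([A–Z0–9]², 1358 chains total); the bundled
  reader understands it, and single-character files remain fully
  standard.
* Alternate locations keep the highest-occupancy conformer (tie: first in
  file).

## Known limitations

* No mmCIF input and no space-group symmetry expansion beyond
  user-supplied rotations/translations; generating a hexamer from a
  one-subunit asymmetric unit is the caller's (or the validation
  script's) responsibility.
* The SASA engine targets assemblies of tens of thousands of atoms;
  it is not tuned for very large complexes.
* Hydrogen-bond detection is geometric and heavy-atom only; no energetic
  scoring, water-mediated contacts or ligand placement.
* Tube models are rigid-body constructions: no relaxation of the
  inter-hexamer angle, no energetic optimisation, and no modelling of the
  pentamer-capped vertices of closed microcompartment shells.
* TEM wall-to-wall diameters are not uniquely comparable to model
  diameters; all three conventions (centreline, outer, lumen) are always
  reported and none is silently equated with a measured value. The
  closed-form centreline diameter of the 12-ring at native spacing
  (≈26 nm) exceeds typical stained-tube measurements (≈20 nm); the
  discrepancy is reported, not reconciled.
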
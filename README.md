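# hexshell

Interface burial, symmetry and nanotube geometry of hexameric bacterial
microcompartment (BMC) shell proteins.

BMC shells are tiled from flat hexamers of Pfam 00936-domain proteins such
as PduA, the major facet protein of the 1,2-propanediol-utilization
metabolosome. In crystals, native PduA hexamers pack into hexagonal sheets
with a centre-to-centre spacing of 67.2 Å; in the bacterial cytoplasm the
same protein assembles into nanotubes roughly 20 nm across. `hexshell`
provides the computational toolkit for reasoning about how a flat hexagonal
sheet of hexamers curves into such tubes, and about which interface residues
hold the tiling together:

* **Surface-area accounting** — a deterministic Shrake–Rupley-style
  solvent-accessible surface area (SASA) engine with a generalized-spiral
  point set; per-residue burial upon assembly (ΔASA), two-sided buried
  interface area `BSA = ASA(A) + ASA(B) − ASA(AB)`, and interface hot-spot
  ranking weighted by distance to the inter-hexamer 2-fold (dyad) axis.
* **Symmetry analysis** — C*n* axis fitting and a symmetry-deviation score
  that is exactly zero for a perfect hexamer and grows with coordinate
  noise; pore-axis profiling and the three opposite-subunit cross
  separations whose inequality diagnoses 6-fold symmetry breaking.
* **Tiling and tubes** — hexagonal sheet construction, classification of
  centre arrangements as 0-, 1- (strip) or 2-dimensional (sheet) tilings,
  and two nanotube architectures: even-*N* ring stacks, where *N* hexamers
  per turn require a polygon interior angle of (*N*−2)·180°/*N* and a
  tilt of 360°/*N* between neighbours (150° and 30° for *N* = 12, 72
  subunits per turn), and multi-start helical wraps of the sheet lattice.
* **Contacts and conservation** — heavy-atom hydrogen-bond inventories
  across interfaces with native-versus-mutant comparison tables, and
  alignment-column conservation mapped to reference residue numbering.
* **Synthetic data** — a coarse-grained, exactly C6-symmetric wedge-shaped
  hexamer generator with labelled interface markers (residues 22, 26, 51,
  79) and a pore loop (residue 40), plus TEM-style diameter measurement
  samples and alignment fixtures, so the entire pipeline is testable
  without downloads.

## Worked example

Build a three-ring stack of the twelve-hexamer tube from the synthetic
hexamer and validate it:

```sh
$ hexshell build-models --synthetic --mode ring --n 12 --rings 3 \
      --out ring.pdb --geometry-json ring.json
wrote ring.pdb (36 hexamers, 0 clashes, contact 1.00) and ring.json
```

The geometry block of `ring.json` reads:

```json
{
  "n_per_turn": 12,
  "interior_angle_deg": 150.0,
  "tilt_deg": 30.0,
  "centerline_radius_A": 129.8204310532508,
  "diameter_nm": {
    "centerline": 25.96408621065016,
    "outer": 29.96408621065016,
    "lumen": 21.96408621065016,
    "convention": "centerline"
  },
  "pitch_A": null,
  "subunit_count": 72
}
```

Twelve hexamers per turn force a 150° interior angle, so successive
hexamers tilt by 30° — an angle the wedge-beveled hexamer edge absorbs
without distortion (`clash_count` 0) while the residue-26 interface
contact survives in every adjacent pair (`contact_preservation` 1.0).
Diameters are reported under all three conventions (centreline, outer
wall, lumen) because a stained TEM wall-to-wall measurement does not map
uniquely onto any one of them.

Symmetry breaking is quantified the same way:

```sh
$ hexshell symmetry --synthetic --perturb-sigma 0.3 --seed 4 --out sym.json
wrote sym.json (deviation 0.521 A)
```

An unperturbed hexamer scores 0; Gaussian coordinate noise of σ per
coordinate scores about σ√3 (here 0.52 Å at σ = 0.3), and the score is
invariant under rigid motion of the whole model.

Other entry points: `hexshell interface-report` (sheet-context ΔASA
ranking and an aspartate-substitution disruptiveness table),
`hexshell simulate` (synthetic structures, TEM-style diameter samples in
the conventional "20.4 ± 1.1 nm (20 measurements)" format, alignment
fixtures) and `hexshell conservation` (column conservation at reference
positions).

## Layout

```
src/hexshell/
  structio.py    PDB I/O, rigid transforms, crystal cells, lattice translations
  synthgen.py    synthetic hexamers, perturbations, measurement samples, MSAs
  surfarea.py    SASA engine, ΔASA, buried surface area, hot-spot ranking
  symtile.py     symmetry fitting, sheets, tiling dimensionality
  tubemodel.py   ring-stack and helical tube builders, clash/contact checks
  porecontact.py hydrogen bonds, interface comparison, pore profiles
  consmap.py     alignment reading and column conservation
  cli.py         command-line interface
```

See `docs/methods.md` for the geometric model, parameter choices and
limitations.
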
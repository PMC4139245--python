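"""Synthetic input generators.

The generators emit the structural features the downstream analyses rely on,
without pretending to be all-atom proteins:

* :func:`make_ideal_hexamer` builds a coarse-grained, exactly C6-symmetric
  wedge-shaped disc of pseudo-atoms — six identical chains related by 60°
  rotations about z, a concave (+z) and convex (-z) face, a central pore
  lined by residue-40 amide markers, and labelled interface marker residues
  (22, 26, 51, 79) placed on the outer edge so that two hexamers set
  67.2 angstrom apart make genuine residue-26 contacts, and the residue-79
  "arm" protrudes beyond the hexagonal body the way the arginine does in the
  real shell protein.
* :func:`perturb_hexamer` breaks the 6-fold symmetry with seeded Gaussian
  coordinate noise (the degraded-symmetry situation seen for interface
  mutants).
* :func:`sample_diameters` emulates TEM diameter measurement samples and
  reports them in the conventional "mean ± sd (n measurements)" style.
* :func:`make_alignment_fixture` writes aligned-FASTA fixtures with chosen
  conserved columns for the conservation-mapping stage.

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, ValidationError
from .structio import Atom, StructureModel, vdw_radius

#: Default roles of the marker residues, keyed by author-style residue number.
DEFAULT_MARKERS = {
    22: "dyad-acidic",
    26: "dyad-contact",
    40: "pore-loop",
    51: "mid-edge",
    79: "protruding-arm",
}


@dataclass(frozen=True)
class HexamerSpec:
    """Geometry of the idealized coarse-grained hexamer.

    ``outer_radius`` is the circumradius of the hexagonal body (vertex to
    centre); the flat-edge apothem is ``outer_radius * cos 30°``.  The
    defaults are frozen so that hexamers tiled at the native 67.2-angstrom
    centre spacing touch through their marker residues without steric
    clashes.
    """

    outer_radius: float = 37.0  # circumradius, angstrom (disc ~74 A across)
    thickness: float = 20.0
    bevel_angle: float = 30.0  # full wedge angle of the beveled edge
    atoms_per_subunit: int = 90  # approximate body atom budget
    pore_radius: float = 4.5  # radius of the residue-40 marker circle
    concave_sagitta: float = 4.0  # depth of the concave-face dome
    marker_positions: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_radius <= self.thickness / 2:
            raise ValidationError("outer_radius must exceed half the thickness")
        if len(set(self.marker_positions)) != len(self.marker_positions):
            raise ValidationError("marker positions must be distinct")

    @property
    def apothem(self) -> float:
        return self.outer_radius * math.cos(math.pi / 6)


# Marker layout within the 60-degree wedge of subunit 0 (angles are measured
# from the subunit's own edge-normal direction, theta = 0).  Radii are
# fractions of the z = 0 edge apothem so the layout scales with the spec.
# 26 sits closest to the inter-subunit boundary and the inter-hexamer dyad,
# then 51 mid-edge, then the 79 arm, which protrudes radially past the body.
_MARKER_LAYOUT = {
    # res: (residue name, [(atom name, element, theta_deg, radial fraction)])
    22: ("ASP", [("CG", "C", 6.5, 0.945), ("OD1", "O", 7.5, 0.985)]),
    26: ("LYS", [("CE", "C", 2.0, 0.952), ("NZ", "N", 2.0, 1.006)]),
    51: ("VAL", [("CB", "C", 15.0, 0.955)]),
    79: (
        "ARG",
        [
            ("CD", "C", 24.0, 1.02),
            ("NE", "N", 25.0, 1.075),
            ("CZ", "C", 25.5, 1.13),
            ("NH1", "N", 27.0, 1.175),
            ("NH2", "N", 24.0, 1.175),
        ],
    ),
}
_MARKER_EDGE_RADIUS_FRACTION = 32.0 / 32.04  # reference marker radius over apothem


def _subunit_atoms(spec: HexamerSpec) -> list[tuple[str, str, int, str, np.ndarray]]:
    """Pseudo-atoms of subunit 0: (atom name, element, resnum, resname, xyz)."""
    half = spec.thickness / 2.0
    taper = math.tan(math.radians(spec.bevel_angle / 2.0))
    apothem0 = spec.apothem
    margin = 1.5  # body inset from the hexagon outline, angstrom

    # choose a grid pitch that lands near the requested atom budget
    wedge_area = (math.pi / 3) * (apothem0**2 - (spec.pore_radius + 2.5) ** 2) / 2
    pitch = max(2.5, math.sqrt(3 * wedge_area / max(spec.atoms_per_subunit, 6)))

    atoms: list[tuple[str, str, int, str, np.ndarray]] = []
    resnum = 101  # body residues numbered away from the marker numbers
    r_inner = spec.pore_radius + 2.5
    for layer, z0 in enumerate((-half, 0.0, half)):
        apothem_z = apothem0 - abs(z0) * taper
        r = r_inner
        while r < apothem_z:
            n_arc = max(1, int(round(r * (math.pi / 3) / pitch)))
            for j in range(n_arc):
                theta = (j + 0.5) * (math.pi / 3) / n_arc
                # stay inside both flat edges of the hexagon (normals at 0/60 deg)
                lim0 = r * math.cos(theta)
                lim60 = r * math.cos(theta - math.pi / 3)
                if max(lim0, lim60) > apothem_z - margin:
                    continue
                z = z0
                if layer != 1:
                    # dome both faces downward: concave top, convex bottom
                    z -= spec.concave_sagitta * max(
                        0.0, 1.0 - (r / spec.outer_radius) ** 2
                    )
                atoms.append(
                    (
                        "X",
                        "C",
                        resnum,
                        "ALA",
                        np.array([r * math.cos(theta), r * math.sin(theta), z]),
                    )
                )
                resnum += 1
            r += pitch

    # marker residues sit at the body's mean height so they stay on the
    # mid-surface used for radial placement in curved assemblies
    z_mark = float(np.mean([pos[2] for *_, pos in atoms])) if atoms else 0.0
    scale = apothem0 * _MARKER_EDGE_RADIUS_FRACTION
    for res, role in spec.marker_positions.items():
        if role == "pore-loop" or res == 40:
            theta = math.radians(30.0)
            pos = np.array(
                [
                    spec.pore_radius * math.cos(theta),
                    spec.pore_radius * math.sin(theta),
                    z_mark + 2.0,
                ]
            )
            atoms.append(("N", "N", res, "SER", pos))
            continue
        if res not in _MARKER_LAYOUT:
            raise GenerationError(
                f"no layout for marker residue {res} ({role}); "
                f"known markers: {sorted(_MARKER_LAYOUT)}"
            )
        resname, sites = _MARKER_LAYOUT[res]
        for atom_name, element, theta_deg, frac in sites:
            theta = math.radians(theta_deg)
            r = frac * scale
            atoms.append(
                (
                    atom_name,
                    element,
                    res,
                    resname,
                    np.array([r * math.cos(theta), r * math.sin(theta), z_mark]),
                )
            )
    return atoms


def make_ideal_hexamer(spec: HexamerSpec | None = None) -> StructureModel:
    """Build the exactly C6-symmetric coarse-grained hexamer.

    Returns a six-chain model (chains A-F); chain k is the seed subunit
    rotated by k*60 degrees about z.  The +z face is concave, -z convex.
    """
    spec = spec or HexamerSpec()
    subunit = _subunit_atoms(spec)

    # marker collision guard (markers only; body grid is collision-free by
    # construction)
    marker_pos = np.array(
        [pos for name, el, res, rn, pos in subunit if res in spec.marker_positions]
    )
    if len(marker_pos) > 1:
        d = np.linalg.norm(marker_pos[:, None] - marker_pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1.0:
            raise GenerationError(
                f"marker pseudo-atoms collide (min distance {d.min():.2f} A < 1 A)"
            )

    atoms: list[Atom] = []
    serial = 1
    for k in range(6):
        c, s = math.cos(k * math.pi / 3), math.sin(k * math.pi / 3)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        chain = "ABCDEF"[k]
        for name, element, resnum, resname, pos in subunit:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_number=resnum,
                    residue_name=resname,
                    chain_id=chain,
                    position=rot @ pos,
                    vdw_radius=vdw_radius(element),
                )
            )
            serial += 1
    model = StructureModel.from_atoms(atoms, label="ideal_hexamer")
    model.chain_groups = {c: 0 for c in "ABCDEF"}
    return model


def perturb_hexamer(model: StructureModel, sigma: float, seed: int) -> StructureModel:
    """Add i.i.d. zero-mean Gaussian noise (std ``sigma`` per coordinate)."""
    if sigma < 0:
        raise ValidationError("perturbation sigma must be non-negative")
    out = model.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        out.coords = model.coords + rng.normal(0.0, sigma, size=model.coords.shape)
    out.label = f"{model.label}_sigma{sigma:g}"
    return out


@dataclass(frozen=True)
class MeasurementSample:
    """A sample of length measurements (nm), e.g. tube diameters from TEM."""

    values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValidationError("a measurement sample needs at least one value")
        if np.any(v <= 0):
            raise ValidationError("measured lengths must be positive")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample standard deviation (ddof=1); 0 for a single measurement."""
        return float(np.std(self.values, ddof=1)) if self.n > 1 else 0.0

    def summary(self, unit: str = "nm") -> str:
        """Report in the conventional ``m ± s <unit> (n measurements)`` style."""
        return f"{self.mean:.1f} ± {self.sd:.1f} {unit} ({self.n} measurements)"


def sample_diameters(
    mean: float, sd: float, n: int, seed: int = 0
) -> MeasurementSample:
    """Draw ``n`` diameters from Normal(mean, sd), emulating a TEM sample."""
    if mean <= 0:
        raise ValidationError("mean diameter must be positive")
    if sd < 0:
        raise ValidationError("diameter sd must be non-negative")
    if n < 1:
        raise ValidationError("sample size must be at least 1")
    rng = np.random.default_rng(seed)
    values = rng.normal(mean, sd, size=n)
    values = np.clip(values, 1e-6, None)  # physical lengths are positive
    return MeasurementSample(values=values, seed=seed)


def measurements_to_tsv(sample: MeasurementSample) -> str:
    lines = ["index\tdiameter_nm"]
    lines += [f"{i + 1}\t{v:.3f}" for i, v in enumerate(sample.values)]
    lines.append(f"# {sample.summary()}")
    return "\n".join(lines) + "\n"


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_alignment_fixture(
    n_sequences: int,
    length: int,
    conserved_columns: dict[int, str] | None = None,
    seed: int = 0,
    gap_fraction: float = 0.0,
) -> str:
    """Aligned-FASTA text with chosen columns identical across sequences.

    ``conserved_columns`` maps 1-based column indices to the residue letter
    fixed there; all other columns are drawn uniformly from the 20-letter
    alphabet, with ``gap_fraction`` of them replaced by gaps.
    """
    conserved_columns = conserved_columns or {}
    if n_sequences < 1 or length < 1:
        raise ValidationError("need at least one sequence and one column")
    for col in conserved_columns:
        if not 1 <= col <= length:
            raise ValidationError(
                f"conserved column {col} outside alignment length {length}"
            )
    if not 0.0 <= gap_fraction < 1.0:
        raise ValidationError("gap_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_sequences):
        letters = rng.choice(list(_AA20), size=length)
        if gap_fraction > 0:
            gaps = rng.random(length) < gap_fraction
            letters = np.where(gaps, "-", letters)
        for col, letter in conserved_columns.items():
            letters[col - 1] = letter.upper()
        records.append((f"seq{i + 1}", "".join(letters)))
    return "".join(f">{name}\n{seq}\n" for name, seq in records)
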
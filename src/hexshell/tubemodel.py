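"""Nanotube architectures from hexagonal shell-protein sheets.

Rolling a hexagonally tiled sheet of hexamers into a tube can be done two
ways, and both are built here:

* **Ring stacks** (:func:`build_ring_tube`): closed rings of N hexamers whose
  vertices interdigitate between successive rings, which forces N to be even.
  Around a ring the hexamer centres form a regular N-gon with interior angle
  (N-2)*180/N, so each hexamer is tilted by 360/N relative to its neighbour
  — for N = 12 an interior angle of 150° and a 30° tilt, which the
  wedge-beveled hexamer edge accommodates without distortion.
* **Multi-start helices** (:func:`build_helical_tube`): interleaved helical
  strands of hexamers, azimuth step 360/N and rise pitch/N per hexamer.  The
  centreline radius is chosen so consecutive strand hexamers keep the lattice
  spacing exactly; strand offsets place the inter-strand neighbours on the
  rolled hexagonal lattice, so every in-sheet contact survives the rolling.

In both modes hexamer 6-fold axes are radial with the concave face pointing
outward, and the builders are fully deterministic.  Clash checking and
marker-contact preservation quantify that the inter-hexamer interactions of
the flat sheet survive in the curved assemblies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError, ValidationError
from .structio import RigidTransform, StructureModel, apply_transform, chain_label
from .symtile import align_axis_to_z, hexamer_centers


@dataclass(frozen=True)
class TubeSpec:
    mode: Literal["ring", "helix"] = "ring"
    n_per_turn: int = 12
    spacing: float = 67.2
    n_turns_or_rings: int = 1
    n_starts: int = 2  # helix only
    pitch: float | None = None  # helix only; None -> n_starts * row spacing
    diameter_convention: Literal["centerline", "outer", "lumen"] = "centerline"

    def __post_init__(self) -> None:
        if self.mode not in ("ring", "helix"):
            raise ValidationError(f"unknown tube mode {self.mode!r}")
        if self.n_per_turn < 3:
            raise ValidationError("need at least 3 hexamers per turn")
        if self.spacing <= 0:
            raise ValidationError("hexamer spacing must be positive")
        if self.n_turns_or_rings < 1:
            raise ValidationError("need at least one ring / turn")
        if self.mode == "ring" and self.n_per_turn % 2 != 0:
            raise ValidationError(
                f"ring mode requires an even number of hexamers per turn "
                f"(got {self.n_per_turn}): successive rings interdigitate their "
                "vertices, which only closes for even counts"
            )
        if self.mode == "helix" and self.n_starts < 1:
            raise ValidationError("helix needs at least one start")
        if self.pitch is not None and self.pitch <= 0:
            raise ValidationError("pitch override must be positive")


@dataclass(frozen=True)
class TubeGeometry:
    """Closed-form geometry of a tube with ``n_per_turn`` hexamers per turn."""

    n_per_turn: int
    interior_angle: float  # degrees
    tilt: float  # degrees, between adjacent hexamer axes
    centerline_radius: float  # angstrom
    diameter_centerline_nm: float
    diameter_outer_nm: float
    diameter_lumen_nm: float
    diameter_convention: str
    pitch: float | None  # angstrom (helix), None for rings
    subunit_count: int  # per turn / ring

    @property
    def diameter_nm(self) -> float:
        return {
            "centerline": self.diameter_centerline_nm,
            "outer": self.diameter_outer_nm,
            "lumen": self.diameter_lumen_nm,
        }[self.diameter_convention]

    def to_dict(self) -> dict:
        return {
            "n_per_turn": self.n_per_turn,
            "interior_angle_deg": self.interior_angle,
            "tilt_deg": self.tilt,
            "centerline_radius_A": self.centerline_radius,
            "diameter_nm": {
                "centerline": self.diameter_centerline_nm,
                "outer": self.diameter_outer_nm,
                "lumen": self.diameter_lumen_nm,
                "convention": self.diameter_convention,
            },
            "pitch_A": self.pitch,
            "subunit_count": self.subunit_count,
        }


def ring_geometry(
    n_per_turn: int,
    spacing: float = 67.2,
    thickness_estimate: float = 20.0,
    diameter_convention: str = "centerline",
    pitch: float | None = None,
) -> TubeGeometry:
    """Polygon geometry of a ring of ``n_per_turn`` hexamers.

    The centres form a regular polygon of side ``spacing``: interior angle
    (n-2)*180/n, tilt between neighbours 360/n, circumradius
    spacing / (2 sin(180/n)).  Wall-to-wall diameters depend on what one
    measures against (stain boundary, lumen, centreline), so all three
    conventions are reported explicitly; none is silently equated with a
    TEM value.
    """
    if n_per_turn < 3:
        raise ValidationError("a ring needs at least 3 hexamers")
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    interior = (n_per_turn - 2) * 180.0 / n_per_turn
    tilt = 360.0 / n_per_turn
    radius = spacing / (2.0 * math.sin(math.pi / n_per_turn))
    return TubeGeometry(
        n_per_turn=n_per_turn,
        interior_angle=interior,
        tilt=tilt,
        centerline_radius=radius,
        diameter_centerline_nm=2 * radius / 10.0,
        diameter_outer_nm=(2 * radius + 2 * thickness_estimate) / 10.0,
        diameter_lumen_nm=(2 * radius - 2 * thickness_estimate) / 10.0,
        diameter_convention=diameter_convention,
        pitch=pitch,
        subunit_count=6 * n_per_turn,
    )


def _radial_frame(phi: float, in_plane_rotation: float = 0.0) -> np.ndarray:
    """Rotation mapping hexamer frame (x, y, z) to (tangential, axial, radial).

    The hexamer's +z (concave face) maps to the outward radial direction;
    ``in_plane_rotation`` (radians) spins the hexamer about its own axis
    first (used to follow the helical lattice direction).
    """
    r_hat = np.array([math.cos(phi), math.sin(phi), 0.0])
    t_hat = np.array([-math.sin(phi), math.cos(phi), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    frame = np.column_stack([t_hat, z_hat, r_hat])
    c, s = math.cos(in_plane_rotation), math.sin(in_plane_rotation)
    spin = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return frame @ spin


def _place_copies(
    base: StructureModel,
    placements: list[tuple[np.ndarray, np.ndarray]],
    label: str,
) -> StructureModel:
    copies = []
    counter = 0
    for group, (rotation, center) in enumerate(placements):
        t = RigidTransform(rotation, center)
        copy = apply_transform(base, t)
        mapping = {}
        for c in copy.chains:
            mapping[c] = chain_label(counter)
            counter += 1
        copy = copy.relabel_chains(mapping)
        copy.chain_groups = {mapping[c]: group for c in mapping}
        copies.append(copy)
    out = StructureModel.concatenate(copies, label=label)
    return out


def build_ring_tube(hexamer: StructureModel, spec: TubeSpec) -> StructureModel:
    """Stack of closed ``n_per_turn``-hexamer rings (``spec.mode == 'ring'``).

    Each ring places the hexamers on the centreline circle with their 6-fold
    axes radial (concave face outward); successive rings are offset half an
    azimuthal step (vertex interdigitation) and spacing*sqrt(3)/2 axially —
    the hexagonal row spacing, so inter-ring neighbours sit at the lattice
    spacing too.
    """
    if spec.mode != "ring":
        raise ValidationError("build_ring_tube needs a ring-mode TubeSpec")
    base = align_axis_to_z(hexamer, order=6)
    n = spec.n_per_turn
    geom = ring_geometry(n, spec.spacing)
    radius = geom.centerline_radius
    rise = spec.spacing * math.sqrt(3) / 2.0
    placements = []
    for ring in range(spec.n_turns_or_rings):
        for k in range(n):
            phi = (k + 0.5 * (ring % 2)) * 2.0 * math.pi / n
            rot = _radial_frame(phi)
            center = np.array(
                [radius * math.cos(phi), radius * math.sin(phi), ring * rise]
            )
            placements.append((rot, center))
    return _place_copies(
        base, placements, label=f"ring_tube_n{n}_r{spec.n_turns_or_rings}"
    )


def build_helical_tube(hexamer: StructureModel, spec: TubeSpec) -> StructureModel:
    """Multi-start helical tube (``spec.mode == 'helix'``).

    Strand geometry: azimuth step 360/n per hexamer, rise pitch/n, with
    pitch defaulting to n_starts times the hexagonal row spacing
    (spacing*sqrt(3)/2) and overridable.  The centreline radius is set so
    consecutive strand hexamers are exactly ``spacing`` apart; each further
    start is offset along the second lattice direction (the strand step
    rotated by 60° on the tube surface), which keeps all in-sheet neighbour
    contacts.  Hexamers lean by the helix angle so their planes follow the
    strand.
    """
    if spec.mode != "helix":
        raise ValidationError("build_helical_tube needs a helix-mode TubeSpec")
    base = align_axis_to_z(hexamer, order=6)
    lat = _helical_lattice(spec)
    placements = []
    for start in range(spec.n_starts):
        for i in range(spec.n_per_turn * spec.n_turns_or_rings):
            arc, z = i * lat.a1 + start * lat.a2
            phi = arc / lat.radius
            rot = _radial_frame(phi, in_plane_rotation=lat.chi)
            center = np.array(
                [lat.radius * math.cos(phi), lat.radius * math.sin(phi), z]
            )
            placements.append((rot, center))
    return _place_copies(
        base,
        placements,
        label=f"helix_tube_n{spec.n_per_turn}_s{spec.n_starts}",
    )


@dataclass(frozen=True)
class _HelicalLattice:
    a1: np.ndarray  # strand step on the unrolled surface (arc, z), angstrom
    a2: np.ndarray  # start-to-start offset on the unrolled surface
    radius: float  # centreline radius, angstrom
    chi: float  # helix angle of the strand, radians
    rise: float  # axial rise per hexamer along a strand
    strand_pitch: float  # axial rise of one strand per full turn


def _helical_lattice(spec: TubeSpec) -> _HelicalLattice:
    """Wrap-closed helical lattice realizing the requested tube parameters.

    The strands and their offsets form a lattice on the unrolled cylinder
    surface; for the tube to be free of seam artifacts the circumference
    vector must itself be a lattice vector (m * a1 - n_starts * a2 with zero
    axial component).  With the hexagonal lattice intact (a2 = a1 rotated by
    60°) that closure fixes the rise per hexamer:

        rise = spacing * (q * sqrt(3) / 2) / sqrt((m - q/2)^2 + 3 q^2 / 4)

    with q = n_starts and m = round(n_per_turn + q/2).  A pitch override
    keeps the strand spacing and closure but stretches the axial component
    of the start offset (the inter-row spacing), which is the only way a
    prescribed pitch can coexist with closed wrapping at fixed spacing.
    """
    n, q, s = spec.n_per_turn, spec.n_starts, spec.spacing
    m = round(n + q / 2.0)
    denom = math.sqrt((m - q / 2.0) ** 2 + 3.0 * q * q / 4.0)
    sqrt3 = math.sqrt(3.0)

    def geometry(rise: float) -> tuple[np.ndarray, np.ndarray, float]:
        a = math.sqrt(s * s - rise * rise)
        a1 = np.array([a, rise])
        a2 = np.array([0.5 * a - sqrt3 / 2.0 * rise, sqrt3 / 2.0 * a + 0.5 * rise])
        return a1, a2, a

    if spec.pitch is None:
        rise = s * (q * sqrt3 / 2.0) / denom
        a1, a2, a = geometry(rise)
        lam = 1.0
    else:
        # solve strand_pitch(rise) = pitch; per-turn count depends on rise too
        from scipy.optimize import brentq

        def pitch_of(rise: float) -> float:
            a = math.sqrt(s * s - rise * rise)
            per_turn = (m - q / 2.0) + (q * sqrt3 / 2.0) * rise / a
            return rise * per_turn

        hi = 0.95 * s
        if pitch_of(hi) < spec.pitch:
            raise ValidationError(
                f"pitch {spec.pitch} A not achievable with spacing {s} A"
            )
        rise = float(brentq(lambda r: pitch_of(r) - spec.pitch, 1e-9, hi, xtol=1e-12))
        a1, a2, a = geometry(rise)
        lam = m * rise / (q * a2[1])
        a2 = np.array([a2[0], lam * a2[1]])
    arc_circumference = m * a1[0] - q * a2[0]
    radius = arc_circumference / (2.0 * math.pi)
    chi = math.atan2(a1[1], a1[0])
    per_turn = arc_circumference / a1[0]
    return _HelicalLattice(
        a1=a1,
        a2=a2,
        radius=radius,
        chi=chi,
        rise=float(a1[1]),
        strand_pitch=float(a1[1]) * per_turn,
    )


def helix_geometry(spec: TubeSpec, thickness_estimate: float = 20.0) -> TubeGeometry:
    """Geometry summary of a helical tube spec (closed-form conventions)."""
    if spec.mode != "helix":
        raise ValidationError("helix_geometry needs a helix-mode TubeSpec")
    pitch = spec.pitch if spec.pitch is not None else spec.n_starts * spec.spacing * math.sqrt(3) / 2.0
    geom = ring_geometry(
        spec.n_per_turn,
        spec.spacing,
        thickness_estimate,
        spec.diameter_convention,
        pitch=pitch,
    )
    return geom


def clash_check(
    assembly: StructureModel, overlap_fraction: float = 0.6
) -> list[tuple[int, int, float]]:
    """Steric clashes between different hexamer copies.

    Returns (atom index, atom index, distance) for pairs from different
    chain groups closer than ``overlap_fraction`` times the sum of their van
    der Waals radii.  Copies are identified by ``chain_groups`` (each chain
    its own copy when the annotation is absent).
    """
    if len(assembly.chains) < 2:
        raise ValidationError("clash check needs an assembly of at least 2 chains")
    if assembly.chain_groups:
        group_of = {c: g for c, g in assembly.chain_groups.items()}
    else:
        group_of = {c: i for i, c in enumerate(assembly.chains)}
    atom_group = np.array([group_of.get(str(c), -1) for c in assembly.chain_ids])
    cutoff = overlap_fraction * 2.0 * assembly.radii.max()
    tree = cKDTree(assembly.coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: list[tuple[int, int, float]] = []
    for i, j in pairs:
        if atom_group[i] == atom_group[j]:
            continue
        d = float(np.linalg.norm(assembly.coords[i] - assembly.coords[j]))
        if d < overlap_fraction * (assembly.radii[i] + assembly.radii[j]):
            out.append((int(i), int(j), d))
    return out


def contact_preservation(
    assembly: StructureModel,
    marker_residue: int = 26,
    contact_cutoff: float = 6.0,
    adjacency_factor: float = 1.25,
) -> float:
    """Fraction of adjacent hexamer pairs whose marker residues stay in contact.

    Adjacency: hexamer centre distance below ``adjacency_factor`` times the
    minimum centre spacing of the assembly.  A pair counts as preserved when
    the closest marker-marker distance across its interface is at most the
    cutoff.
    """
    marker_mask = assembly.res_numbers == marker_residue
    if not marker_mask.any():
        raise SelectionError(
            f"marker residue {marker_residue} absent from the assembly"
        )
    centers = hexamer_centers(assembly)
    if centers.shape[0] < 2:
        raise ValidationError("need at least two hexamer copies")
    groups = sorted(set(assembly.chain_groups.values()))
    group_of = {c: g for c, g in assembly.chain_groups.items()}
    atom_group = np.array([group_of[str(c)] for c in assembly.chain_ids])

    dist = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    iu = np.triu_indices(len(groups), k=1)
    dmin = dist[iu].min()
    preserved = 0
    total = 0
    for a_idx, b_idx in zip(*iu):
        if dist[a_idx, b_idx] >= adjacency_factor * dmin:
            continue
        total += 1
        ma = marker_mask & (atom_group == groups[a_idx])
        mb = marker_mask & (atom_group == groups[b_idx])
        d = np.linalg.norm(
            assembly.coords[ma][:, None] - assembly.coords[mb][None, :], axis=-1
        )
        if d.min() <= contact_cutoff:
            preserved += 1
    if total == 0:
        raise ValidationError("no adjacent hexamer pairs found")
    return preserved / total
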
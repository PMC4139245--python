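"""Pore-axis geometry and interface hydrogen-bond inventories.

Hydrogen bonds are detected at the heavy-atom level (deposited shell-protein
structures carry no hydrogens): donor/acceptor N/O pairs within a distance
cutoff, optionally filtered by the antecedent-donor-acceptor angle, and
classified by the relationship of their partners (same chain, same hexamer,
or across hexamers).  The pore profile samples the largest probe sphere that
fits on the 6-fold axis at each height, and the three cross-axis separations
between the pore-loop atoms of opposite subunits diagnose symmetry breaking:
they are equal exactly when the pore lining is 6-fold symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError, ValidationError
from .structio import StructureModel
from .symtile import SymmetryFit

HBondClass = Literal["intra-subunit", "intra-hexamer", "inter-hexamer"]


@dataclass(frozen=True)
class HBond:
    donor_index: int
    acceptor_index: int
    donor_chain: str
    donor_residue: int
    donor_residue_name: str
    donor_atom: str
    acceptor_chain: str
    acceptor_residue: int
    acceptor_residue_name: str
    acceptor_atom: str
    distance: float
    bond_class: HBondClass

    @property
    def key(self) -> tuple:
        """(donor residue, acceptor residue, class) identity for comparisons."""
        return (
            (self.donor_residue_name, self.donor_residue, self.donor_atom),
            (self.acceptor_residue_name, self.acceptor_residue, self.acceptor_atom),
            self.bond_class,
        )


def _classify(
    model: StructureModel, i: int, j: int, group_of: dict[str, int]
) -> HBondClass:
    ci, cj = str(model.chain_ids[i]), str(model.chain_ids[j])
    if ci == cj:
        return "intra-subunit"
    if group_of.get(ci) == group_of.get(cj) and ci in group_of and cj in group_of:
        return "intra-hexamer"
    return "inter-hexamer"


def detect_hbonds(
    assembly: StructureModel,
    d_max: float = 3.5,
    require_geometry: bool = False,
    d_min: float = 2.2,
) -> list[HBond]:
    """Heavy-atom hydrogen bonds in ``assembly``.

    Candidate partners are N/O atoms between ``d_min`` (below which a pair is
    covalent or clashing, and 1-2/1-3 neighbours within a residue are always
    excluded) and ``d_max`` apart.  With ``require_geometry`` the angle at
    the donor between its covalent antecedent and the acceptor must be at
    least 90°, a proxy for a plausible inferred hydrogen position.  Bonds are
    reported once, nitrogen preferred as donor.
    """
    if d_max <= 0:
        raise ValidationError("d_max must be positive")
    polar = np.isin(assembly.elements.astype(str), ["N", "O"])
    idx = np.nonzero(polar)[0]
    if idx.size == 0:
        return []
    coords = assembly.coords[idx]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(d_max, output_type="ndarray")
    group_of = dict(assembly.chain_groups)
    if not group_of:
        group_of = {c: k for k, c in enumerate(assembly.chains)}

    full_tree = cKDTree(assembly.coords) if require_geometry else None
    bonds: list[HBond] = []
    for a, b in pairs:
        i, j = int(idx[a]), int(idx[b])
        same_res = (
            assembly.chain_ids[i] == assembly.chain_ids[j]
            and assembly.res_numbers[i] == assembly.res_numbers[j]
        )
        if same_res:
            continue
        d = float(np.linalg.norm(assembly.coords[i] - assembly.coords[j]))
        if d < d_min:
            continue
        # nitrogen preferred as donor; ambiguous pairs keep index order
        ei, ej = str(assembly.elements[i]), str(assembly.elements[j])
        if ei != "N" and ej == "N":
            i, j = j, i
        if require_geometry and not _antecedent_angle_ok(assembly, full_tree, i, j):
            continue
        bonds.append(
            HBond(
                donor_index=i,
                acceptor_index=j,
                donor_chain=str(assembly.chain_ids[i]),
                donor_residue=int(assembly.res_numbers[i]),
                donor_residue_name=str(assembly.res_names[i]),
                donor_atom=str(assembly.names[i]),
                acceptor_chain=str(assembly.chain_ids[j]),
                acceptor_residue=int(assembly.res_numbers[j]),
                acceptor_residue_name=str(assembly.res_names[j]),
                acceptor_atom=str(assembly.names[j]),
                distance=d,
                bond_class=_classify(assembly, i, j, group_of),
            )
        )
    bonds.sort(key=lambda h: (h.donor_chain, h.donor_residue, h.acceptor_chain, h.acceptor_residue, h.distance))
    return bonds


def _antecedent_angle_ok(
    model: StructureModel, tree: cKDTree, donor: int, acceptor: int
) -> bool:
    """Antecedent-donor-acceptor angle >= 90° for every covalent antecedent.

    Antecedents are atoms of the same residue within covalent range (1.9 A).
    A donor with no antecedent (isolated pseudo-atom) passes by default.
    """
    near = tree.query_ball_point(model.coords[donor], 1.9)
    angles_ok = True
    found = False
    for k in near:
        if k == donor or k == acceptor:
            continue
        if (
            model.chain_ids[k] != model.chain_ids[donor]
            or model.res_numbers[k] != model.res_numbers[donor]
        ):
            continue
        found = True
        v1 = model.coords[k] - model.coords[donor]
        v2 = model.coords[acceptor] - model.coords[donor]
        cosang = float(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        )
        if cosang > 0.0:  # angle < 90°
            angles_ok = False
    return angles_ok or not found


@dataclass
class InterfaceComparison:
    shared: list[tuple]
    only_a: list[tuple]
    only_b: list[tuple]


def compare_interfaces(
    report_a: list[HBond], report_b: list[HBond]
) -> InterfaceComparison:
    """Difference table of two hydrogen-bond inventories.

    Bonds are keyed by (donor residue, acceptor residue, class); the output
    lists are sorted for deterministic reporting.
    """
    keys_a = {h.key for h in report_a}
    keys_b = {h.key for h in report_b}
    return InterfaceComparison(
        shared=sorted(keys_a & keys_b),
        only_a=sorted(keys_a - keys_b),
        only_b=sorted(keys_b - keys_a),
    )


@dataclass
class PoreProfile:
    """Pore radius along the symmetry axis plus opposite-subunit separations."""

    samples: list[tuple[float, float]]  # (axial position A, pore radius A)
    min_radius: float
    cross_separations: dict[tuple[str, str], float]

    @property
    def anisotropy(self) -> float:
        """Max minus min cross separation; zero for an exact C6 pore lining."""
        values = list(self.cross_separations.values())
        return max(values) - min(values)

    def to_tsv(self) -> str:
        lines = ["z_A\tpore_radius_A"]
        lines += [f"{z:.2f}\t{r:.3f}" for z, r in self.samples]
        return "\n".join(lines) + "\n"


def pore_profile(
    hexamer: StructureModel,
    axis: SymmetryFit,
    step: float = 0.5,
    loop_atom_spec: tuple[int, str] = (40, "N"),
) -> PoreProfile:
    """Profile of the central pore along the fitted symmetry axis.

    At each axial sample the pore radius is the clearance of the axis point:
    min over atoms of (distance to the point minus the atom's van der Waals
    radius), floored at 0.  ``cross_separations`` holds the three distances
    between the designated pore-loop atom of chain k and chain k+3 —
    opposite subunits of the rotationally ordered hexamer.
    """
    chains = hexamer.chains
    if len(chains) != 6:
        raise ValidationError(f"pore profile needs a 6-chain hexamer (got {len(chains)})")
    if step <= 0:
        raise ValidationError("axial step must be positive")
    resnum, atom_name = loop_atom_spec
    loop_pos: dict[str, np.ndarray] = {}
    for c in chains:
        mask = (
            (hexamer.chain_ids == c)
            & (hexamer.res_numbers == int(resnum))
            & (hexamer.names == atom_name)
        )
        if not mask.any():
            raise SelectionError(
                f"pore-loop atom {atom_name} of residue {resnum} missing in chain {c}"
            )
        loop_pos[c] = hexamer.coords[mask][0]

    u = axis.axis_direction
    rel = hexamer.coords - axis.center
    axial = rel @ u
    lo, hi = float(axial.min()), float(axial.max())
    samples: list[tuple[float, float]] = []
    n_steps = max(1, int(math.ceil((hi - lo) / step)))
    for k in range(n_steps + 1):
        z = lo + k * (hi - lo) / n_steps
        point = axis.center + z * u
        clearance = np.linalg.norm(hexamer.coords - point, axis=1) - hexamer.radii
        samples.append((z, float(max(0.0, clearance.min()))))

    cross: dict[tuple[str, str], float] = {}
    for k in range(3):
        a, b = chains[k], chains[k + 3]
        cross[(a, b)] = float(np.linalg.norm(loop_pos[a] - loop_pos[b]))
    return PoreProfile(
        samples=samples,
        min_radius=min(r for _, r in samples),
        cross_separations=cross,
    )


@dataclass
class ProbeFitResult:
    probe_radius: float
    passes: list[bool]  # one per axial sample
    spans_thickness: bool  # continuous passing corridor across the hexamer


def probe_fit(profile: PoreProfile, probe_radius: float) -> ProbeFitResult:
    """Which axial samples admit a spherical probe of ``probe_radius``.

    ``spans_thickness`` is true when every sample from the first to the last
    passes, i.e. the corridor is continuous through the hexamer.
    """
    if probe_radius < 0:
        raise ValidationError("probe radius must be non-negative")
    if not profile.samples:
        raise ValidationError("empty pore profile")
    passes = [r >= probe_radius for _, r in profile.samples]
    return ProbeFitResult(
        probe_radius=probe_radius,
        passes=passes,
        spans_thickness=all(passes),
    )
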
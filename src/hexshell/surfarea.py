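"""Solvent-accessible surface area, interface burial and hot-spot ranking.

The SASA engine is a Shrake–Rupley-style point-sampling method with a
deterministic generalized-spiral point set on each probe-expanded sphere, so
results are bit-reproducible at a fixed point count.  The accessible area of
an atom is the fraction of its sphere points not inside any other
probe-expanded sphere, times 4*pi*(r + p)^2.  Exactly coincident identical
atoms split their surface symmetrically (each point on the boundary counts
half).

On top of the engine sit the assembly-analysis operations: per-residue loss
of accessibility on assembly (ΔASA), two-sided buried surface area
BSA = ASA(A) + ASA(B) - ASA(AB), and interface hot-spot ranking with the
distance of each residue's side-chain terminus to its image under the
inter-hexamer dyad (residues near the 2-fold meet their own symmetry mate,
which is what makes like-charge substitutions there maximally disruptive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError, ValidationError
from .structio import RigidTransform, StructureModel

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9

#: Side-chain terminal atom used for dyad-distance measurements; residues
#: without an entry fall back to their side-chain centroid.
TERMINAL_ATOMS = {
    "LYS": "NZ",
    "ARG": "CZ",
    "VAL": "CB",
    "ASP": "CG",
    "GLU": "CD",
    "SER": "OG",
    "THR": "OG1",
    "ASN": "CG",
    "GLN": "CD",
    "LEU": "CG",
    "ILE": "CD1",
    "MET": "SD",
    "PHE": "CZ",
    "TYR": "OH",
    "TRP": "CZ2",
    "HIS": "NE2",
    "CYS": "SG",
    "PRO": "CG",
}
_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


def spiral_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) points on the unit sphere."""
    if n < 1:
        raise ValidationError("need at least one sphere point")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class AreaReport:
    """Accessible-area bookkeeping for one model."""

    per_atom: np.ndarray  # accessible area per atom, A^2
    per_residue: dict[tuple[str, int], float]
    total: float
    probe_radius: float
    n_points: int

    def residue_area(self, chain: str, residue_number: int) -> float:
        return self.per_residue[(chain, int(residue_number))]


def compute_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    include_het: bool = False,
) -> AreaReport:
    """Accessible surface area of every (protein) atom of ``model``.

    HETATM entries are excluded by default: the analyses here are protein
    surfaces, and ligands/solvent would silently shrink them.
    """
    if probe_radius < 0:
        raise ValidationError("probe radius must be non-negative")
    if n_points < 60:
        raise ValidationError(
            f"n_points = {n_points} is too coarse for meaningful areas (need >= 60)"
        )
    work = model if include_het or not model.het.any() else model.subset(~model.het)

    pts = spiral_points(n_points)
    coords = work.coords
    expanded = work.radii + probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    per_atom = np.empty(len(work))
    for i in range(len(work)):
        r_i = expanded[i]
        neighbors = tree.query_ball_point(coords[i], r_i + expanded.max())
        neighbors = [j for j in neighbors if j != i]
        sphere = coords[i] + r_i * pts
        if neighbors:
            d = np.linalg.norm(
                sphere[:, None, :] - coords[neighbors][None, :, :], axis=-1
            )
            margin = d - expanded[neighbors][None, :]
            min_margin = margin.min(axis=1)
            acc = np.where(
                min_margin < -_TIE_TOL,
                0.0,
                np.where(min_margin <= _TIE_TOL, 0.5, 1.0),
            )
            frac = acc.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * math.pi * r_i * r_i

    # map back onto the full atom list (het atoms get area 0, not absent)
    if work is not model:
        full = np.zeros(len(model))
        full[~model.het] = per_atom
        per_atom = full

    per_residue: dict[tuple[str, int], float] = {}
    for key in model.residue_keys():
        chain, resnum = key
        mask = (model.chain_ids == chain) & (model.res_numbers == resnum)
        per_residue[key] = float(per_atom[mask].sum())
    return AreaReport(
        per_atom=per_atom,
        per_residue=per_residue,
        total=float(per_atom.sum()),
        probe_radius=probe_radius,
        n_points=n_points,
    )


def monte_carlo_sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_samples: int = 1_000_000,
    seed: int = 0,
    include_het: bool = False,
) -> float:
    """Brute-force Monte-Carlo surface integration (independent oracle).

    Random points are thrown uniformly on every probe-expanded sphere and the
    exposed fraction integrated.  Slow and noisy by design; used to check the
    deterministic engine, never to replace it.
    """
    work = model if include_het or not model.het.any() else model.subset(~model.het)
    rng = np.random.default_rng(seed)
    coords = work.coords
    expanded = work.radii + probe_radius
    areas = 4.0 * math.pi * expanded**2
    per_sphere = np.maximum(1, (n_samples * areas / areas.sum()).astype(int))
    total = 0.0
    for i in range(len(work)):
        m = per_sphere[i]
        v = rng.normal(size=(m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sphere = coords[i] + expanded[i] * v
        exposed = np.ones(m, dtype=bool)
        for j in range(len(work)):
            if j == i:
                continue
            exposed &= (
                np.linalg.norm(sphere - coords[j], axis=1) >= expanded[j]
            )
        total += exposed.mean() * areas[i]
    return float(total)


def delta_asa(
    unit: StructureModel,
    assembly: StructureModel,
    unit_selector: set[str] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[tuple[str, int], float]:
    """Per-residue loss of accessible area when ``unit`` sits in ``assembly``.

    ``unit_selector`` names the chains of ``assembly`` that correspond to
    ``unit`` (defaults to the unit's own chain ids).  Small negative
    differences are point-sampling noise and are floored at zero (counted
    and logged).
    """
    selector = set(unit_selector) if unit_selector is not None else set(unit.chains)
    missing = selector - set(assembly.chains)
    if missing:
        raise SelectionError(
            f"selector chains {sorted(missing)} absent from the assembly"
        )
    sel_mask = np.array([c in selector for c in assembly.chain_ids])
    if sel_mask.sum() != len(unit):
        raise ValidationError(
            f"selector covers {int(sel_mask.sum())} assembly atoms but the unit has "
            f"{len(unit)}; chain correspondence is broken"
        )
    rmsd = float(
        np.sqrt(np.mean(np.sum((assembly.coords[sel_mask] - unit.coords) ** 2, axis=1)))
    )
    if rmsd > 0.1:
        raise ValidationError(
            f"unit coordinates differ from their assembly copy (RMSD {rmsd:.3f} A > 0.1)"
        )

    iso = compute_sasa(unit, probe_radius, n_points)
    ctx = compute_sasa(assembly, probe_radius, n_points)
    out: dict[tuple[str, int], float] = {}
    floored = 0
    for key, area in iso.per_residue.items():
        d = area - ctx.per_residue[key]
        if d < 0:
            floored += 1
            d = 0.0
        out[key] = d
    if floored:
        logger.debug("delta_asa floored %d small negative differences at 0", floored)
    return out


def buried_surface_area(
    part_a: StructureModel,
    part_b: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Two-sided buried area ASA(A) + ASA(B) - ASA(A∪B), in A^2.

    The two-sided convention counts the burial on both partners, matching how
    interface areas of shell-protein edges are usually quoted.
    """
    if set(part_a.chains) & set(part_b.chains):
        mapping = {}
        used = set(part_a.chains)
        i = 0
        for c in part_b.chains:
            new = c
            while new in used:
                new = f"{'abcdefghijklmnopqrstuvwxyz'[i % 26]}{i // 26 if i >= 26 else ''}"
                i += 1
            mapping[c] = new
            used.add(new)
        part_b = part_b.relabel_chains(mapping)
    # duplicate guard: mostly-overlapping parts are almost certainly the same model twice
    tree = cKDTree(part_b.coords)
    d, _ = tree.query(part_a.coords)
    clash_frac = float(np.mean(d < 0.5 * (part_a.radii + part_b.radii.mean())))
    if clash_frac > 0.5:
        raise ValidationError(
            f"{clash_frac:.0%} of atoms in part A clash with part B; "
            "the two parts look like duplicates of the same model"
        )
    asa_a = compute_sasa(part_a, probe_radius, n_points).total
    asa_b = compute_sasa(part_b, probe_radius, n_points).total
    both = StructureModel.concatenate([part_a, part_b])
    asa_ab = compute_sasa(both, probe_radius, n_points).total
    return asa_a + asa_b - asa_ab


@dataclass(frozen=True)
class HotspotEntry:
    chain: str
    residue_number: int
    residue_name: str
    delta_asa: float
    dyad_distance: float


@dataclass
class HotspotRanking:
    """Interface residues ordered by ΔASA (ties: residue number ascending)."""

    entries: list[HotspotEntry]
    context_label: str = "sheet"

    def to_tsv(self) -> str:
        lines = ["rank\tchain\tresidue_number\tresidue_name\tdelta_asa_A2\tdyad_distance_A"]
        for rank, e in enumerate(self.entries, start=1):
            lines.append(
                f"{rank}\t{e.chain}\t{e.residue_number}\t{e.residue_name}"
                f"\t{e.delta_asa:.1f}\t{e.dyad_distance:.2f}"
            )
        return "\n".join(lines) + "\n"


def _terminal_position(model: StructureModel, chain: str, resnum: int) -> np.ndarray:
    mask = (model.chain_ids == chain) & (model.res_numbers == resnum)
    if not mask.any():
        raise SelectionError(f"residue {chain}/{resnum} not found")
    res_name = str(model.res_names[mask][0])
    names = model.names[mask]
    coords = model.coords[mask]
    wanted = TERMINAL_ATOMS.get(res_name)
    if wanted is not None and wanted in names:
        return coords[list(names).index(wanted)]
    side = ~np.isin(names.astype(str), list(_BACKBONE))
    if side.any():
        return coords[side].mean(axis=0)
    return coords.mean(axis=0)


def rank_interface_hotspots(
    hexamer: StructureModel,
    assembly: StructureModel,
    dyad: RigidTransform,
    probe_radius: float = 1.4,
    n_points: int = 960,
    context_label: str = "sheet",
    min_delta: float = 1.0,
) -> HotspotRanking:
    """Rank residues of ``hexamer`` by burial in ``assembly``.

    ``dyad`` must be the 2-fold relating adjacent hexamers; each entry
    carries the distance between the residue's side-chain terminus and its
    dyad image.  Residues whose ΔASA is below ``min_delta`` (sampling noise)
    are omitted.
    """
    twice = dyad.compose(dyad)
    if not (
        np.allclose(twice.rotation, np.eye(3), atol=1e-6)
        and np.allclose(twice.translation, 0.0, atol=1e-6)
    ):
        raise ValidationError("dyad transform is not of order 2 (dyad^2 != identity)")
    d_asa = delta_asa(hexamer, assembly, probe_radius=probe_radius, n_points=n_points)
    entries: list[HotspotEntry] = []
    for (chain, resnum), value in d_asa.items():
        if value < min_delta:
            continue
        mask = (hexamer.chain_ids == chain) & (hexamer.res_numbers == resnum)
        res_name = str(hexamer.res_names[mask][0])
        pos = _terminal_position(hexamer, chain, resnum)
        image = dyad.apply(pos[None, :])[0]
        entries.append(
            HotspotEntry(
                chain=chain,
                residue_number=resnum,
                residue_name=res_name,
                delta_asa=float(value),
                dyad_distance=float(np.linalg.norm(image - pos)),
            )
        )
    entries.sort(key=lambda e: (-e.delta_asa, e.residue_number))
    return HotspotRanking(entries=entries, context_label=context_label)
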
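"""Structure and crystal-cell I/O, rigid transforms and lattice translations.

The in-memory currency of the package is :class:`StructureModel`, a compact
array-backed container (coordinates and van der Waals radii as numpy arrays,
per-atom annotations as object arrays) in Cartesian angstroms.  PDB files are
read and written with the classic fixed-column layout; assemblies with more
than 62 chains use a documented two-character chain-identifier extension
(columns 21-22), which is why the reader/writer pair lives here rather than
behind a third-party parser — round-tripping our own large assemblies is part
of the contract.  Crystal cells follow the standard crystallographic
orthogonalization convention (**a** along x, **b** in the xy-plane).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import (
    CapacityError,
    EmptyStructureError,
    InputError,
    PDBParseError,
    ValidationError,
)

#: Default element -> van der Waals radius table (angstrom).  These are the
#: common Bondi-style values; AREAIMOL-era programs used slightly different
#: radii, so the table is overridable (see :func:`load_config`).
DEFAULT_VDW = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_RADIUS = 1.70  # pseudo-atoms and unknown elements

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

# Single-character chain alphabet (62 symbols), then a two-character scheme:
# labels 63.. are written as two characters from [A-Z0-9] in PDB columns
# 21-22 (the column directly left of the official chain-id column plus the
# official column itself).  The reader understands both.
_CHAIN1 = string.ascii_uppercase + string.ascii_lowercase + string.digits
_CHAIN2 = string.ascii_uppercase + string.digits


def chain_label(index: int) -> str:
    """Deterministic chain label for the ``index``-th chain (0-based)."""
    if index < 0:
        raise ValidationError("chain index must be non-negative")
    if index < len(_CHAIN1):
        return _CHAIN1[index]
    i = index - len(_CHAIN1)
    n = len(_CHAIN2)
    if i >= n * n:
        raise CapacityError(
            f"chain index {index} exceeds the two-character labelling scheme "
            f"({len(_CHAIN1) + n * n} chains); split the assembly across files"
        )
    return _CHAIN2[i // n] + _CHAIN2[i % n]


def vdw_radius(element: str, table: Mapping[str, float] | None = None) -> float:
    table = DEFAULT_VDW if table is None else table
    return float(table.get(element.upper(), DEFAULT_RADIUS))


@dataclass(frozen=True)
class Atom:
    """Read-only view of one atom of a :class:`StructureModel`."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    vdw_radius: float
    het: bool = False


@dataclass(frozen=True)
class CrystalCell:
    """Unit-cell parameters (angstrom / degrees) plus the space-group label."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group_label: str = "P 1"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValidationError(f"cell angle {name} must lie in (0, 180) degrees")

    @property
    def orthogonalization(self) -> np.ndarray:
        """Fractional -> Cartesian matrix, **a** along x, **b** in xy."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg, sg = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
        v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in angstroms."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValidationError("rotation matrix is not orthonormal (tol 1e-9)")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise ValidationError("rotation determinant must be +1 (proper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translation_by(cls, t: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def rotation_about_axis(
        cls,
        axis: Sequence[float],
        angle_deg: float,
        center: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a line through ``center``."""
        u = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(u)
        if norm == 0:
            raise ValidationError("rotation axis must be non-zero")
        u = u / norm
        th = math.radians(angle_deg)
        k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        r = np.eye(3) + math.sin(th) * k + (1 - math.cos(th)) * (k @ k)
        c = np.asarray(center, dtype=float)
        return cls(r, c - r @ c)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass
class StructureModel:
    """Array-backed molecular model.

    Parallel arrays hold one entry per atom; ``chain_groups`` optionally maps a
    chain id to the index of the rigid copy (e.g. hexamer) it belongs to, which
    downstream clash/contact analyses use to tell copies apart.
    """

    serials: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    res_numbers: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    radii: np.ndarray
    het: np.ndarray
    label: str = ""
    cell: CrystalCell | None = None
    chain_groups: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n == 0:
            raise EmptyStructureError("a StructureModel must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("atom coordinates must be finite")
        self.radii = np.asarray(self.radii, dtype=float).reshape(n)
        if np.any(self.radii <= 0):
            raise ValidationError("van der Waals radii must be positive")
        for name in ("serials", "names", "elements", "res_numbers", "res_names", "chain_ids", "het"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValidationError(f"field {name} has {arr.shape[0]} entries for {n} atoms")
            setattr(self, name, arr)

    # ---- construction helpers -------------------------------------------

    @classmethod
    def from_atoms(
        cls,
        atoms: Iterable[Atom],
        label: str = "",
        cell: CrystalCell | None = None,
    ) -> "StructureModel":
        atoms = list(atoms)
        return cls(
            serials=np.array([a.serial for a in atoms], dtype=int),
            names=np.array([a.name for a in atoms], dtype=object),
            elements=np.array([a.element for a in atoms], dtype=object),
            res_numbers=np.array([a.residue_number for a in atoms], dtype=int),
            res_names=np.array([a.residue_name for a in atoms], dtype=object),
            chain_ids=np.array([a.chain_id for a in atoms], dtype=object),
            coords=np.array([a.position for a in atoms], dtype=float),
            radii=np.array([a.vdw_radius for a in atoms], dtype=float),
            het=np.array([a.het for a in atoms], dtype=bool),
            label=label,
            cell=cell,
        )

    @classmethod
    def concatenate(
        cls, models: Sequence["StructureModel"], label: str = ""
    ) -> "StructureModel":
        """Merge models; chain ids must already be disjoint between models."""
        seen: set[str] = set()
        for m in models:
            ids = set(m.chains)
            if ids & seen:
                raise ValidationError(
                    f"chain ids {sorted(ids & seen)} appear in more than one part; "
                    "relabel before concatenating"
                )
            seen |= ids
        groups: dict[str, int] = {}
        for m in models:
            groups.update(m.chain_groups)
        return cls(
            serials=np.concatenate([m.serials for m in models]),
            names=np.concatenate([m.names for m in models]),
            elements=np.concatenate([m.elements for m in models]),
            res_numbers=np.concatenate([m.res_numbers for m in models]),
            res_names=np.concatenate([m.res_names for m in models]),
            chain_ids=np.concatenate([m.chain_ids for m in models]),
            coords=np.vstack([m.coords for m in models]),
            radii=np.concatenate([m.radii for m in models]),
            het=np.concatenate([m.het for m in models]),
            label=label or models[0].label,
            cell=models[0].cell,
            chain_groups=groups,
        )

    # ---- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)

    def atoms(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield Atom(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_number=int(self.res_numbers[i]),
                residue_name=str(self.res_names[i]),
                chain_id=str(self.chain_ids[i]),
                position=self.coords[i].copy(),
                vdw_radius=float(self.radii[i]),
                het=bool(self.het[i]),
            )

    def subset(self, mask: np.ndarray, label: str | None = None) -> "StructureModel":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise EmptyStructureError("selection matched no atoms")
        m = replace(
            self,
            serials=self.serials[mask],
            names=self.names[mask],
            elements=self.elements[mask],
            res_numbers=self.res_numbers[mask],
            res_names=self.res_names[mask],
            chain_ids=self.chain_ids[mask],
            coords=self.coords[mask],
            radii=self.radii[mask],
            het=self.het[mask],
            label=self.label if label is None else label,
        )
        kept = set(m.chains)
        m.chain_groups = {c: g for c, g in self.chain_groups.items() if c in kept}
        return m

    def select(
        self,
        chain_ids: Iterable[str] | None = None,
        residue_numbers: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        include_het: bool = True,
    ) -> "StructureModel":
        mask = np.ones(len(self), dtype=bool)
        if chain_ids is not None:
            wanted = set(chain_ids)
            mask &= np.array([c in wanted for c in self.chain_ids])
        if residue_numbers is not None:
            wanted_r = set(int(r) for r in residue_numbers)
            mask &= np.array([int(r) in wanted_r for r in self.res_numbers])
        if atom_names is not None:
            wanted_n = set(atom_names)
            mask &= np.array([n in wanted_n for n in self.names])
        if not include_het:
            mask &= ~self.het
        return self.subset(mask)

    def center(self, weights: np.ndarray | None = None) -> np.ndarray:
        return np.average(self.coords, axis=0, weights=weights)

    def copy(self) -> "StructureModel":
        return replace(
            self,
            serials=self.serials.copy(),
            names=self.names.copy(),
            elements=self.elements.copy(),
            res_numbers=self.res_numbers.copy(),
            res_names=self.res_names.copy(),
            chain_ids=self.chain_ids.copy(),
            coords=self.coords.copy(),
            radii=self.radii.copy(),
            het=self.het.copy(),
            chain_groups=dict(self.chain_groups),
        )

    def relabel_chains(self, mapping: Mapping[str, str]) -> "StructureModel":
        m = self.copy()
        m.chain_ids = np.array([mapping.get(c, c) for c in self.chain_ids], dtype=object)
        m.chain_groups = {mapping.get(c, c): g for c, g in self.chain_groups.items()}
        return m

    def residue_keys(self) -> list[tuple[str, int]]:
        """(chain, residue_number) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.res_numbers):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    for two in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        if name.upper().startswith(two):
            return two.capitalize()
    return name[0].upper()


def read_structure(
    path: str | Path,
    radii_table: Mapping[str, float] | None = None,
) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    ATOM records are kept in file order; HETATM records are retained and
    flagged.  A CRYST1 record, when present, is attached as a
    :class:`CrystalCell`.  Alternate locations keep the highest-occupancy
    conformer (ties: first in file).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc

    atoms: list[Atom] = []
    occupancies: list[float] = []
    altlocs: list[str] = []
    cell: CrystalCell | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "CRYST1":
            try:
                cell = CrystalCell(
                    a=float(line[6:15]),
                    b=float(line[15:24]),
                    c=float(line[24:33]),
                    alpha=float(line[33:40]),
                    beta=float(line[40:47]),
                    gamma=float(line[47:54]),
                    space_group_label=line[55:66].strip() or "P 1",
                )
            except (ValueError, ValidationError) as exc:
                raise PDBParseError(f"bad CRYST1 record: {exc}", lineno) from exc
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"malformed coordinate field: {line[30:54]!r}", lineno) from exc
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = len(atoms) + 1
        name = line[12:16].strip()
        altloc = line[16]
        res_name = line[17:20].strip()
        # two-character chain extension: column 21 (index 20) is normally
        # blank; when populated it is the first character of the chain id.
        chain = (line[20].strip() + line[21].strip()) or "A"
        try:
            res_number = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"malformed residue number: {line[22:26]!r}", lineno) from exc
        try:
            occ = float(line[54:60])
        except (ValueError, IndexError):
            occ = 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
        element = element.capitalize() if element else _guess_element(name)
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_number=res_number,
                residue_name=res_name,
                chain_id=chain,
                position=np.array([x, y, z]),
                vdw_radius=vdw_radius(element, radii_table),
                het=(rec == "HETATM"),
            )
        )
        occupancies.append(occ)
        altlocs.append(altloc)

    if not atoms:
        raise EmptyStructureError(f"{path} contains no ATOM records")

    atoms = _resolve_altlocs(atoms, altlocs, occupancies)
    return StructureModel.from_atoms(atoms, label=path.stem, cell=cell)


def _resolve_altlocs(
    atoms: list[Atom], altlocs: list[str], occupancies: list[float]
) -> list[Atom]:
    """Keep the highest-occupancy alternate conformer (tie -> first in file)."""
    best: dict[tuple, int] = {}
    plain: list[int] = []
    for i, (atom, alt, occ) in enumerate(zip(atoms, altlocs, occupancies)):
        if alt == " ":
            plain.append(i)
            continue
        key = (atom.chain_id, atom.residue_number, atom.name)
        if key not in best or occ > occupancies[best[key]]:
            best[key] = i
    keep = sorted(plain + list(best.values()))
    return [atoms[i] for i in keep]


def write_structure(model: StructureModel, path: str | Path) -> Path:
    """Write a fixed-column PDB file (CRYST1 when a cell is attached,
    TER between chains, END terminator)."""
    if model.n_atoms >= 100000:
        raise CapacityError(
            f"{model.n_atoms} atoms exceed the 5-digit PDB serial field; "
            "split the assembly into several output models"
        )
    path = Path(path)
    lines: list[str] = []
    if model.cell is not None:
        c = model.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} {c.space_group_label:<11s}"
        )
    serial = 0
    prev_chain: str | None = None
    for atom in model.atoms():
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        serial += 1
        rec = "HETATM" if atom.het else "ATOM  "
        name = atom.name
        # conventional alignment: 1/2-letter elements start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
        chain = atom.chain_id
        if len(chain) == 1:
            chain_field = " " + chain
        elif len(chain) == 2:
            chain_field = chain
        else:
            raise CapacityError(f"chain id {chain!r} longer than two characters")
        x, y, z = atom.position
        lines.append(
            f"{rec}{serial:5d} {name_field} {atom.residue_name:>3s}{chain_field}"
            f"{atom.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Transforms and lattice geometry
# ---------------------------------------------------------------------------


def apply_transform(model: StructureModel, t: RigidTransform) -> StructureModel:
    """Return a copy of ``model`` moved by the rigid transform ``t``."""
    out = model.copy()
    out.coords = t.apply(model.coords)
    return out


def lattice_translation_length(
    cell: CrystalCell, indices: Sequence[int]
) -> float:
    """Length of the lattice translation ``u a + v b + w c`` in angstrom."""
    u, v, w = (int(i) for i in indices)
    if u == 0 and v == 0 and w == 0:
        raise ValidationError("lattice index triple must not be (0, 0, 0)")
    vec = cell.orthogonalization @ np.array([u, v, w], dtype=float)
    return float(np.linalg.norm(vec))


def expand_neighbors(
    model: StructureModel,
    cell: CrystalCell,
    index_list: Sequence[Sequence[int]],
) -> StructureModel:
    """Place one copy of ``model`` at each lattice translation in ``index_list``.

    Chains of every copy are relabelled uniquely (see :func:`chain_label`);
    ``chain_groups`` records which copy each chain belongs to.  The copy at
    (0, 0, 0), when requested, is geometrically identical to the input.
    """
    triples = [tuple(int(i) for i in idx) for idx in index_list]
    if len(set(triples)) != len(triples):
        raise ValidationError("duplicate lattice index triples in expansion list")
    ortho = cell.orthogonalization
    copies: list[StructureModel] = []
    chain_counter = 0
    for group, triple in enumerate(triples):
        shift = ortho @ np.array(triple, dtype=float)
        copy = apply_transform(model, RigidTransform.translation_by(shift))
        mapping = {}
        for c in copy.chains:
            mapping[c] = chain_label(chain_counter)
            chain_counter += 1
        copy = copy.relabel_chains(mapping)
        copy.chain_groups = {mapping[c]: group for c in mapping}
        copies.append(copy)
    out = StructureModel.concatenate(copies, label=f"{model.label}_x{len(triples)}")
    out.cell = cell
    return out


# ---------------------------------------------------------------------------
# Config (radii override etc.)
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a simple ``key = value`` config file (``#`` comments allowed)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"config line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def radii_from_config(config: Mapping[str, str]) -> dict[str, float]:
    """Extract ``radius.<EL> = <value>`` overrides on top of the default table."""
    table = dict(DEFAULT_VDW)
    for key, value in config.items():
        if key.startswith("radius."):
            table[key.split(".", 1)[1].upper()] = float(value)
    return table
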
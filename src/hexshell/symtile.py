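"""Cyclic-symmetry fitting, symmetry-deviation scoring and sheet tiling.

A Cn-symmetric oligomer superposes onto itself after rotation by 360/n about
its symmetry axis with the chains cyclically permuted.  :func:`fit_symmetry_axis`
finds the axis (direction + a point on it) minimizing the mean squared
residual of that self-superposition, over all cyclic chain pairings.  The
reported ``deviation_rmsd`` is the RMS deviation of the atoms from the
pairwise symmetric mean, i.e. ``RMSD(model, rotated model) / sqrt(2)``; it is
zero exactly for a perfect Cn oligomer and, for i.i.d. Gaussian coordinate
noise of standard deviation sigma per coordinate, has expectation
``sigma * sqrt(3)`` — the natural per-structure scale of symmetry breaking.

The module also builds planar hexagonal sheets of hexamers and classifies
arrangements of centers as 0-, 1- (strip) or 2-dimensional (sheet) tilings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import ValidationError
from .structio import RigidTransform, StructureModel, apply_transform, chain_label


@dataclass(frozen=True)
class SymmetryFit:
    axis_direction: np.ndarray  # unit vector
    center: np.ndarray  # a point on the axis, angstrom
    order: int
    deviation_rmsd: float
    per_chain_rmsd: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        u = np.asarray(self.axis_direction, dtype=float).reshape(3)
        object.__setattr__(self, "axis_direction", u / np.linalg.norm(u))
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3)
        )


def _chain_stack(model: StructureModel, order: int) -> np.ndarray:
    chains = model.chains
    if len(chains) != order:
        raise ValidationError(
            f"model has {len(chains)} chains; order-{order} fit needs exactly {order}"
        )
    sizes = []
    stacks = []
    for c in chains:
        mask = model.chain_ids == c
        stacks.append(model.coords[mask])
        sizes.append(int(mask.sum()))
    if len(set(sizes)) != 1:
        raise ValidationError(f"chains have unequal atom counts {sizes}")
    return np.stack(stacks)  # (order, m, 3)


def _unit_from_angles(theta: float, phi: float) -> np.ndarray:
    st = math.sin(theta)
    return np.array([st * math.cos(phi), st * math.sin(phi), math.cos(theta)])


def _rotation_matrix(u: np.ndarray, angle: float) -> np.ndarray:
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _axis_objective(
    u: np.ndarray, angle: float, x: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean squared residual |R(x-c)+c-y|^2 with the optimal center c.

    For fixed axis direction the optimal c solves a linear least-squares
    problem (the component of c along the axis is unconstrained and set by
    the minimum-norm solution).
    """
    r = _rotation_matrix(u, angle)
    a = np.eye(3) - r
    resid = x @ r.T - y  # + a c
    rhs = -resid.mean(axis=0)
    c, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    d = resid + c @ a.T
    return float(np.mean(np.sum(d * d, axis=1))), c


def fit_symmetry_axis(model: StructureModel, order: int) -> SymmetryFit:
    """Fit the Cn axis of an oligomer with ``order`` equal-size chains.

    Chain correspondence under the rotation is restricted to cyclic
    permutations of the chain order (rotationally built oligomers list their
    chains in rotational order; real structures must be pre-sorted the same
    way).
    """
    if order < 2:
        raise ValidationError("symmetry order must be at least 2")
    stack = _chain_stack(model, order)
    x = stack.reshape(-1, 3)
    angle = 2.0 * math.pi / order

    # initial axis: the coordinate direction of least variance (a disc or
    # ring oligomer is thin along its symmetry axis), plus z as a fallback
    centered = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    inits = [vt[-1], np.array([0.0, 0.0, 1.0])]

    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for shift in range(1, order):
        y = np.roll(stack, -shift, axis=0).reshape(-1, 3)
        for u0 in inits:
            theta0 = math.acos(np.clip(u0[2], -1, 1))
            phi0 = math.atan2(u0[1], u0[0])

            def f(p: np.ndarray) -> float:
                return _axis_objective(_unit_from_angles(p[0], p[1]), angle, x, y)[0]

            res = minimize(
                f,
                np.array([theta0, phi0]),
                method="Nelder-Mead",
                options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 2000},
            )
            u = _unit_from_angles(res.x[0], res.x[1])
            val, c = _axis_objective(u, angle, x, y)
            if best is None or val < best[0]:
                best = (val, u, c, shift)

    assert best is not None
    msd, u, c, shift = best
    # deviation from the pairwise symmetric mean: RMSD(model, rotated)/sqrt(2)
    deviation = math.sqrt(max(msd, 0.0) / 2.0)
    r = _rotation_matrix(u, angle)
    y = np.roll(stack, -shift, axis=0)
    per_chain = []
    for k in range(order):
        d = (stack[k] - c) @ r.T + c - y[k]
        per_chain.append(math.sqrt(np.mean(np.sum(d * d, axis=1)) / 2.0))
    if u[2] < 0:  # orient consistently (towards +z when possible)
        u = -u
    return SymmetryFit(
        axis_direction=u,
        center=c,
        order=order,
        deviation_rmsd=deviation,
        per_chain_rmsd=tuple(per_chain),
    )


def symmetry_deviation(model: StructureModel, order: int) -> float:
    """Deviation (angstrom) from exact ``order``-fold symmetry; 0 if perfect."""
    return fit_symmetry_axis(model, order).deviation_rmsd


def align_axis_to_z(model: StructureModel, order: int = 6) -> StructureModel:
    """Rigidly move ``model`` so its fitted Cn axis is z through the origin."""
    fit = fit_symmetry_axis(model, order)
    u = fit.axis_direction
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        r = np.eye(3)
    else:
        k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]) / s
        cth = float(np.dot(u, z))
        r = np.eye(3) + s * k + (1 - cth) * (k @ k)
    t = RigidTransform(r, -r @ fit.center)
    out = apply_transform(model, t)
    out.coords[:, 2] -= out.coords[:, 2].mean()
    return out


@dataclass(frozen=True)
class SheetSpec:
    """Planar hexagonal (p6-packed) sheet of hexamers."""

    spacing: float = 67.2  # centre-to-centre, angstrom
    rows: int = 3
    cols: int = 3

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValidationError("sheet spacing must be positive")
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("sheet needs at least 1 row and 1 column")


def sheet_centers(spec: SheetSpec) -> np.ndarray:
    """Hexamer centre positions of the sheet, one row offset by spacing/2."""
    s = spec.spacing
    centers = []
    for r in range(spec.rows):
        for c in range(spec.cols):
            centers.append([(c + 0.5 * (r % 2)) * s, r * s * math.sqrt(3) / 2, 0.0])
    return np.array(centers)


def build_sheet(hexamer: StructureModel, spec: SheetSpec) -> StructureModel:
    """Tile ``hexamer`` on the hexagonal lattice of ``spec``.

    The hexamer is first aligned so its fitted 6-fold axis is the sheet
    normal; every nearest-neighbour centre distance equals ``spec.spacing``
    exactly.
    """
    base = align_axis_to_z(hexamer, order=6)
    copies = []
    counter = 0
    for group, center in enumerate(sheet_centers(spec)):
        copy = apply_transform(base, RigidTransform.translation_by(center))
        mapping = {}
        for c in copy.chains:
            mapping[c] = chain_label(counter)
            counter += 1
        copy = copy.relabel_chains(mapping)
        copy.chain_groups = {mapping[c]: group for c in mapping}
        copies.append(copy)
    if len(copies) == 1:
        return copies[0]
    return StructureModel.concatenate(
        copies, label=f"sheet_{spec.rows}x{spec.cols}"
    )


def hexamer_centers(assembly: StructureModel) -> np.ndarray:
    """Centres of the rigid copies recorded in ``assembly.chain_groups``."""
    if not assembly.chain_groups:
        raise ValidationError("assembly carries no chain-group annotation")
    groups = sorted(set(assembly.chain_groups.values()))
    centers = []
    for g in groups:
        chains = {c for c, gg in assembly.chain_groups.items() if gg == g}
        mask = np.array([c in chains for c in assembly.chain_ids])
        centers.append(assembly.coords[mask].mean(axis=0))
    return np.array(centers)


def tiling_dimensionality(
    centers: np.ndarray, spacing_tolerance: float = 0.05
) -> int:
    """0, 1 or 2: rank of the span of nearest-neighbour difference vectors.

    Neighbours are pairs within ``(1 + tolerance)`` of the minimum pairwise
    distance; the rank uses a singular-value threshold of 1e-6 of the leading
    singular value.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if centers.shape[0] == 0:
        raise ValidationError("need at least one centre")
    if centers.shape[0] == 1:
        return 0
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(centers.shape[0], k=1)
    dmin = dist[iu].min()
    mask = (dist <= (1.0 + spacing_tolerance) * dmin) & (dist > 0)
    vectors = diff[mask]
    if vectors.size == 0:
        return 0
    s = np.linalg.svd(vectors, compute_uv=False)
    return int(np.sum(s > 1e-6 * s[0]))


def symmetry_report(model: StructureModel, order: int = 6) -> dict:
    """JSON-ready symmetry summary (axis, centre, deviation, per-chain)."""
    fit = fit_symmetry_axis(model, order)
    return {
        "order": fit.order,
        "axis_direction": [float(v) for v in fit.axis_direction],
        "center": [float(v) for v in fit.center],
        "deviation_rmsd_A": float(fit.deviation_rmsd),
        "per_chain_rmsd_A": [float(v) for v in fit.per_chain_rmsd],
    }
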
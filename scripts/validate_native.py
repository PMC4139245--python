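#!/usr/bin/env python
"""Validate the analysis against the deposited native hexamer structure.

Needs a local copy of Protein Data Bank entry 3NGK (the native PduA
hexamer), e.g.::

    curl -O https://files.rcsb.org/download/3NGK.pdb
    python scripts/validate_native.py 3NGK.pdb

The deposited asymmetric unit of the P622 crystal form holds one subunit;
the hexamer is generated here by the crystallographic 6-fold (60-degree
rotations about the c axis), and the sheet context by the in-plane lattice
translations of the hexagonal cell.  Reported quantities, with the
published reference values in parentheses:

* subunit total accessible surface (~20,400 A^2)
* per-subunit burial inside the hexamer (~9,600 A^2)
* two-hexamer interface buried area at the 67.2-A lattice translation
  (~1,200 A^2)
* sheet-context ΔASA of Lys-26 / Arg-79 / Val-51 (77 / 139 / 57 A^2)
* hot-spot ranking (Arg-79 above Lys-26) and lattice spacing (67.2 A)
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np

from hexshell import (
    expand_neighbors,
    read_structure,
)
from hexshell.errors import HexshellError
from hexshell.structio import RigidTransform, StructureModel, apply_transform
from hexshell.surfarea import buried_surface_area, compute_sasa, delta_asa
from hexshell.symtile import hexamer_centers


def build_hexamer(subunit: StructureModel) -> StructureModel:
    copies = []
    for k in range(6):
        t = RigidTransform.rotation_about_axis([0, 0, 1], 60.0 * k)
        copy = apply_transform(subunit, t)
        mapping = {c: "ABCDEF"[k] for c in copy.chains}
        copy = copy.relabel_chains(mapping)
        copy.chain_groups = {"ABCDEF"[k]: 0}
        copies.append(copy)
    hexamer = StructureModel.concatenate(copies, label="native_hexamer")
    hexamer.chain_groups = {c: 0 for c in "ABCDEF"}
    return hexamer


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("pdb", type=Path, help="path to the downloaded 3NGK.pdb")
    parser.add_argument("--n-points", type=int, default=480)
    parser.add_argument("--out", type=Path, default=Path("native_validation.json"))
    args = parser.parse_args()

    model = read_structure(args.pdb)
    if model.het.any():
        model = model.subset(~model.het)
    if len(model.chains) == 1:
        subunit = model
        hexamer = build_hexamer(subunit)
    elif len(model.chains) == 6:
        hexamer = model
        hexamer.chain_groups = {c: 0 for c in hexamer.chains}
        subunit = hexamer.select(chain_ids=[hexamer.chains[0]])
    else:
        print(f"unexpected chain count {len(model.chains)}", file=sys.stderr)
        return 2
    cell = model.cell
    if cell is None:
        print("no CRYST1 cell in the file", file=sys.stderr)
        return 2

    np_ = args.n_points
    results: dict[str, float] = {}
    results["cell_a_axis_A"] = cell.a

    subunit_asa = compute_sasa(subunit, n_points=np_).total
    results["subunit_total_surface_A2"] = subunit_asa
    # one-sided burial on the subunit when it sits inside the hexamer
    in_hex = compute_sasa(hexamer, n_points=np_)
    chain0 = hexamer.chains[0]
    ctx0 = sum(v for (c, r), v in in_hex.per_residue.items() if c == chain0)
    results["subunit_burial_in_hexamer_A2"] = subunit_asa - ctx0

    # sheet context: central hexamer plus six lattice neighbours
    indices = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (1, 1, 0), (-1, -1, 0)]
    sheet = expand_neighbors(hexamer, cell, indices)
    centers = hexamer_centers(sheet)
    results["lattice_spacing_A"] = float(
        np.linalg.norm(centers[1] - centers[0])
    )

    central_chains = [c for c, g in sheet.chain_groups.items() if g == 0]
    d = delta_asa(
        hexamer.relabel_chains(
            dict(zip(hexamer.chains, central_chains))
        ),
        sheet,
        unit_selector=set(central_chains),
        n_points=np_,
    )
    per_res: dict[int, float] = {}
    for (chain, resnum), v in d.items():
        per_res[resnum] = max(per_res.get(resnum, 0.0), v)
    for resnum, label in ((26, "lys26"), (79, "arg79"), (51, "val51")):
        results[f"delta_asa_{label}_A2"] = per_res.get(resnum, 0.0)
    results["ranking_arg79_above_lys26"] = float(
        per_res.get(79, 0.0) > per_res.get(26, 0.0)
    )

    neighbor = apply_transform(
        hexamer, RigidTransform.translation_by(cell.orthogonalization @ [1, 0, 0])
    ).relabel_chains({c: c.lower() for c in hexamer.chains})
    results["pair_interface_bsa_A2"] = buried_surface_area(
        hexamer, neighbor, n_points=np_
    )

    args.out.write_text(json.dumps(results, indent=2) + "\n")
    for k, v in results.items():
        print(f"{k}: {v:.1f}")
    return 0


if __name__ == "__main__":
    try:
        sys.exit(main())
    except HexshellError as exc:
        print(f"error: {exc}", file=sys.stderr)
        sys.exit(2)
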
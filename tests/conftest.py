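import numpy as np
import pytest

from hexshell import (
    HexamerSpec,
    SheetSpec,
    TubeSpec,
    build_ring_tube,
    build_sheet,
    make_ideal_hexamer,
)
from hexshell.structio import Atom, StructureModel
from hexshell.symtile import align_axis_to_z


@pytest.fixture(scope="session")
def ideal_hexamer():
    return make_ideal_hexamer(HexamerSpec(seed=0))


@pytest.fixture(scope="session")
def aligned_hexamer(ideal_hexamer):
    return align_axis_to_z(ideal_hexamer, order=6)


@pytest.fixture(scope="session")
def hexamer_pair(ideal_hexamer):
    """Two hexamers at the native 67.2-angstrom centre spacing."""
    return build_sheet(ideal_hexamer, SheetSpec(spacing=67.2, rows=1, cols=2))


@pytest.fixture(scope="session")
def sheet_3x3(ideal_hexamer):
    return build_sheet(ideal_hexamer, SheetSpec(spacing=67.2, rows=3, cols=3))


@pytest.fixture(scope="session")
def ring_tube(ideal_hexamer):
    return build_ring_tube(
        ideal_hexamer,
        TubeSpec(mode="ring", n_per_turn=12, spacing=67.2, n_turns_or_rings=3),
    )


def make_atoms(coords, radius=1.7, element="C", chain="A"):
    """Small helper for ad-hoc pseudo-structures in tests."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    return StructureModel.from_atoms(
        Atom(
            serial=i + 1,
            name="X",
            element=element,
            residue_number=i + 1,
            residue_name="ALA",
            chain_id=chain,
            position=c,
            vdw_radius=radius,
        )
        for i, c in enumerate(coords)
    )
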
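import io

import numpy as np
import pytest

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from etgating.scales import default_scale


@pytest.fixture(scope="session")
def scale():
    return default_scale()


def make_atom_array(atoms):
    """atoms: list of (chain, res_id, res_name, atom_name, (x, y, z))."""
    arr = struc.AtomArray(len(atoms))
    for i, (chain, rid, rname, aname, xyz) in enumerate(atoms):
        arr.chain_id[i] = chain
        arr.res_id[i] = rid
        arr.res_name[i] = rname
        arr.atom_name[i] = aname
        arr.hetero[i] = False
        arr.element[i] = aname[0]
        arr.coord[i] = xyz
    return arr


def make_pdb_text(atoms):
    pdb = PDBFile()
    pdb.set_structure(make_atom_array(atoms))
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def make_multimodel_pdb_text(models):
    """models: list of atom lists (same atoms, different coordinates)."""
    arrays = [make_atom_array(m) for m in models]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


@pytest.fixture
def two_helix_model():
    """Two ideal parallel poly-Ala helices ~6 A apart, as a StructureModel."""
    from etgating.structure import read_structure

    atoms = []
    rise, turn, radius = 1.5, np.deg2rad(100.0), 2.3
    for chain, offset in (("A", np.array([0.0, 0.0, 0.0])),
                          ("D", np.array([6.0, 0.0, 0.75]))):
        for i in range(12):
            ang = i * turn
            xyz = offset + np.array([radius * np.cos(ang),
                                     radius * np.sin(ang), i * rise])
            atoms.append((chain, 201 + i, "ALA", "CA", xyz))
    return read_structure(make_pdb_text(atoms))
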
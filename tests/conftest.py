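import numpy as np
import pytest

from glycoconf.synthetic import sialyl_lewis_mock

# A two-residue toy disaccharide: ring atoms only, plus the bridge O4 on
# residue 1 needed by the (1->4) linkage quadruples.
_TOY_PDB_TEMPLATE = """\
{records}END
"""


def _pdb_atom(serial, name, resname, chain, resid, x, y, z, element):
    return (
        f"ATOM  {serial:>5} {name:<4}{resname:>3} {chain}{resid:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}\n"
    )


@pytest.fixture
def toy_disaccharide_pdb(tmp_path):
    """12-ring-atom, 2-residue PDB plus linkage bridge atoms."""
    from glycoconf.pucker import invert_cremer_pople

    ring1 = invert_cremer_pople(0.55, 5.0, 30.0) + np.array([0.0, 0.0, 0.0])
    ring2 = invert_cremer_pople(0.55, 5.0, 30.0) + np.array([5.0, 0.0, 0.0])
    names = ["O5", "C1", "C2", "C3", "C4", "C5"]
    records = []
    serial = 1
    for resid, ring in ((1, ring1), (2, ring2)):
        for name, pos in zip(names, ring):
            records.append(
                _pdb_atom(serial, name, "GLC", "A", resid, *pos, name[0])
            )
            serial += 1
    # bridge oxygen O4 on the acceptor residue 1
    records.append(_pdb_atom(serial, "O4", "GLC", "A", 1, 2.5, 1.0, 0.5, "O"))
    path = tmp_path / "toy.pdb"
    path.write_text(_TOY_PDB_TEMPLATE.format(records="".join(records)))
    return path


@pytest.fixture
def toy_topology_config():
    return {
        "rings": [
            {"residue": "A:1", "atoms": ["O5", "C1", "C2", "C3", "C4", "C5"]},
            {"residue": "A:2", "atoms": ["O5", "C1", "C2", "C3", "C4", "C5"]},
        ],
        "linkages": [
            {"donor": "A:2", "acceptor": "A:1", "kind": "1->4"},
        ],
    }


@pytest.fixture(scope="session")
def small_mock_glycan():
    """Light 4-ring mock system shared by I/O- and CLI-level tests."""
    return sialyl_lewis_mock(n_frames=12, n_waters=60, seed=11)
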
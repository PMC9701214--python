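import numpy as np
import pytest

from confdyn.structure_io import POLYMER, AtomRecord, Ensemble
from confdyn.synthetic import build_backbone, build_reference


def backbone_ensemble(phi: np.ndarray, psi: np.ndarray, chain_id: str = "A") -> Ensemble:
    """Ensemble with only N/CA/C backbone atoms built from torsions."""
    coords = build_backbone(phi, psi)
    n_res = coords.shape[1] // 3
    records = []
    serial = 1
    for resnum in range(1, n_res + 1):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C")):
            records.append(
                AtomRecord(serial, name, "GLY", chain_id, resnum, element, POLYMER)
            )
            serial += 1
    return Ensemble(topology=records, coordinates=coords)


@pytest.fixture(scope="session")
def reference_300():
    """Idealized 300-residue reference with donor/acceptor pseudo-atoms."""
    return build_reference(300)


@pytest.fixture(scope="session")
def reference_20():
    return build_reference(20)


TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.458   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.100   3.300   3.000  1.00  0.00           C
ATOM      4  N   GLY A   2       4.400   3.300   3.100  1.00  0.00           N
HETATM    5  N5  FAD A   3      10.000   0.000   0.000  1.00  0.00           N
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       1.100   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.558   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.200   3.300   3.000  1.00  0.00           C
ATOM      4  N   GLY A   2       4.500   3.300   3.100  1.00  0.00           N
HETATM    5  N5  FAD A   3      10.100   0.000   0.000  1.00  0.00           N
ENDMDL
END
"""


@pytest.fixture
def two_model_file(tmp_path):
    path = tmp_path / "two_model.pdb"
    path.write_text(TWO_MODEL_PDB)
    return path
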
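import numpy as np
import pytest

from hingekit import synth

LYS_PDB = """\
ATOM      1  N   LYS A 528      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  LYS A 528      11.458  10.000  10.000  1.00  0.00           C
ATOM      3  C   LYS A 528      12.009  11.420  10.000  1.00  0.00           C
ATOM      4  O   LYS A 528      11.251  12.390  10.000  1.00  0.00           O
ATOM      5  CB  LYS A 528      11.958   9.260   8.760  1.00  0.00           C
ATOM      6  CG  LYS A 528      13.478   9.160   8.680  1.00  0.00           C
ATOM      7  CD  LYS A 528      13.938   8.400   7.440  1.00  0.00           C
ATOM      8  CE  LYS A 528      15.458   8.300   7.360  1.00  0.00           C
ATOM      9  NZ  LYS A 528      15.918   7.560   6.150  1.00  0.00           N
END
"""

ARG_PDB = """\
ATOM      1  N   ARG B  10      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ARG B  10      11.458  10.000  10.000  1.00  0.00           C
ATOM      3  C   ARG B  10      12.009  11.420  10.000  1.00  0.00           C
ATOM      4  O   ARG B  10      11.251  12.390  10.000  1.00  0.00           O
ATOM      5  CB  ARG B  10      11.958   9.260   8.760  1.00  0.00           C
ATOM      6  CG  ARG B  10      13.478   9.160   8.680  1.00  0.00           C
ATOM      7  CD  ARG B  10      13.938   8.400   7.440  1.00  0.00           C
ATOM      8  NE  ARG B  10      15.378   8.300   7.360  1.00  0.00           N
ATOM      9  CZ  ARG B  10      16.048   7.620   6.440  1.00  0.00           C
ATOM     10  NH1 ARG B  10      15.438   6.940   5.480  1.00  0.00           N
ATOM     11  NH2 ARG B  10      17.378   7.600   6.450  1.00  0.00           N
END
"""

# three residues; residue 2 has an altloc A/B pair on CA
ALTLOC_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA AALA A   2       3.800   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   2       3.900   0.100   0.000  0.40  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      5  O   HOH A 100      20.000  20.000  20.000  1.00  0.00           O
HETATM    6 ZN    ZN A 999      30.000  30.000  30.000  1.00  0.00          ZN
END
"""


@pytest.fixture(scope="session")
def lys_structure():
    from hingekit import read_structure
    return read_structure(LYS_PDB)


@pytest.fixture(scope="session")
def arg_structure():
    from hingekit import read_structure
    return read_structure(ARG_PDB)


@pytest.fixture(scope="session")
def hinge60():
    return synth.make_hinge_structure(theta=60.0, seed=11)


@pytest.fixture(scope="session")
def hinge_partition():
    return synth.hinge_partition()


@pytest.fixture(scope="session")
def peptide_complex():
    """10-mer pseudo-peptide; residues 8-10 planned to touch the lid only."""
    return synth.make_peptide_complex(
        contact_plan={8: "lid", 9: "lid", 10: "lid"},
        atoms_per_globule=40, seed=21)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
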
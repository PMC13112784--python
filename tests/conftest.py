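import textwrap

import pytest

from intprof import RuleParameters, VdwRadiusTable, build_registry
from intprof.fixtures import make_toy_complex


@pytest.fixture(scope="session")
def registry():
    return build_registry()


@pytest.fixture()
def params():
    return RuleParameters()


@pytest.fixture()
def radii():
    return VdwRadiusTable.default()


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(seed=0)


@pytest.fixture()
def ala_gly_water_pdb(tmp_path):
    """Minimal PDB: Ala-Gly dipeptide with hydrogens plus one water."""
    text = textwrap.dedent("""\
        ATOM      1  N   ALA A   1      -0.525   1.362   0.000  1.00  0.00           N
        ATOM      2  H   ALA A   1      -0.032   2.237   0.000  1.00  0.00           H
        ATOM      3  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
        ATOM      4  HA  ALA A   1       0.380  -0.310  -0.960  1.00  0.00           H
        ATOM      5  CB  ALA A   1      -1.100  -1.040   0.280  1.00  0.00           C
        ATOM      6  HB1 ALA A   1      -1.910  -0.900  -0.420  1.00  0.00           H
        ATOM      7  HB2 ALA A   1      -0.720  -2.050   0.180  1.00  0.00           H
        ATOM      8  HB3 ALA A   1      -1.470  -0.900   1.290  1.00  0.00           H
        ATOM      9  C   ALA A   1       1.200   0.000   0.940  1.00  0.00           C
        ATOM     10  O   ALA A   1       1.310   0.830   1.840  1.00  0.00           O
        ATOM     11  N   GLY A   2       2.120  -0.940   0.720  1.00  0.00           N
        ATOM     12  H   GLY A   2       1.990  -1.590  -0.040  1.00  0.00           H
        ATOM     13  CA  GLY A   2       3.330  -1.050   1.530  1.00  0.00           C
        ATOM     14  HA2 GLY A   2       3.090  -0.920   2.580  1.00  0.00           H
        ATOM     15  HA3 GLY A   2       3.780  -2.030   1.400  1.00  0.00           H
        ATOM     16  C   GLY A   2       4.330   0.030   1.130  1.00  0.00           C
        ATOM     17  O   GLY A   2       4.120   0.750   0.160  1.00  0.00           O
        TER
        HETATM   18  O   HOH A 101       6.000   3.000   2.000  1.00  0.00           O
        HETATM   19  H1  HOH A 101       6.600   3.600   2.450  1.00  0.00           H
        HETATM   20  H2  HOH A 101       5.400   3.600   1.550  1.00  0.00           H
        END
    """)
    path = tmp_path / "ala_gly_water.pdb"
    path.write_text(text)
    return path


@pytest.fixture()
def rotamer_library_file(tmp_path):
    """Three-rotamer serine bin at (-60, -40) plus a neighboring bin."""
    text = textwrap.dedent("""\
        # synthetic backbone-dependent rotamer library fixture
        SER  -60  -40  100  1 0 0 0  0.600000   62.0    0.0    0.0    0.0  8.0 0.0 0.0 0.0
        SER  -60  -40  100  2 0 0 0  0.300000  -65.0    0.0    0.0    0.0  8.5 0.0 0.0 0.0
        SER  -60  -40  100  3 0 0 0  0.100000  180.0    0.0    0.0    0.0  9.0 0.0 0.0 0.0
        SER  -60  -30   80  1 0 0 0  0.550000   62.5    0.0    0.0    0.0  8.0 0.0 0.0 0.0
        SER  -60  -30   80  2 0 0 0  0.450000  -64.0    0.0    0.0    0.0  8.2 0.0 0.0 0.0
        LEU  -60  -40   90  1 1 0 0  0.700000  -65.0  175.0    0.0    0.0  7.0 7.0 0.0 0.0
        LEU  -60  -40   90  2 2 0 0  0.300000  177.0   65.0    0.0    0.0  7.5 7.5 0.0 0.0
    """)
    path = tmp_path / "rotamers.lib"
    path.write_text(text)
    return path
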
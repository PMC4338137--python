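import numpy as np
import pytest

from pocketeer.pocket_detection import GridParams
from pocketeer.synthetic_fixtures import (
    POCKET_A,
    FixtureSpec,
    make_cup_protein,
    make_shell_protein,
    rim_targets,
)


@pytest.fixture(scope="session")
def cup_spec():
    return FixtureSpec(seed=1, carves=[POCKET_A], polar_sites=[(POCKET_A, "acceptor")])


@pytest.fixture(scope="session")
def cup(cup_spec):
    """Solid pseudo-protein with one carved cylindrical pocket and a
    carbonyl decoration on the pocket wall."""
    return make_cup_protein(cup_spec)


@pytest.fixture(scope="session")
def cup_targets(cup, cup_spec):
    return rim_targets(cup, POCKET_A, outer_radius=cup_spec.shell_radius)


@pytest.fixture(scope="session")
def shell():
    """Convex (pocket-free) solid pseudo-protein."""
    return make_shell_protein(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def grid_params():
    return GridParams(edge_length=14.0, spacing=0.7)


@pytest.fixture(scope="session")
def cup_exemplar(cup, cup_targets, grid_params):
    from pocketeer.exemplar import build_exemplar

    return build_exemplar(cup, cup_targets, grid_params, source="cup")


DIPEPTIDE_PDB = """\
ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  H   GLY A   1       1.000   2.980   3.000  1.00  0.00           H
ATOM      3  CA  GLY A   1       2.450   2.000   3.000  1.00  0.00           C
ATOM      4  C   GLY A   1       3.100   2.000   4.350  1.00  0.00           C
ATOM      5  O   GLY A   1       2.500   2.000   5.420  1.00  0.00           O
ATOM      6  N   SER A   2       4.430   2.000   4.330  1.00  0.00           N
ATOM      7  CA  SER A   2       5.200   2.000   5.560  1.00  0.00           C
ATOM      8  CB  SER A   2       6.690   2.000   5.280  1.00  0.00           C
ATOM      9  OG  SER A   2       7.420   2.000   6.490  1.00  0.00           O
ATOM     10  O   SER A   2       5.210   3.100   7.560  1.00  0.00           O
END
"""


@pytest.fixture()
def dipeptide_pdb():
    return DIPEPTIDE_PDB
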
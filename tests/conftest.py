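import numpy as np
import pytest

import pocketgate as pg

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.000  1.00  0.00           C
ATOM      3  O   ALA A   2       3.500   2.000   4.000  1.00  0.00           O
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def small_structure():
    """A 4-residue mini-chain with backbone + CB atoms."""
    atoms = []
    serial = 0
    names = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]
    rng = np.random.default_rng(42)
    for seq in range(1, 5):
        base = np.array([3.8 * seq, 0.0, 0.0])
        for k, (name, el) in enumerate(names):
            serial += 1
            atoms.append(pg.Atom(serial, name, el, "SER", seq, "A",
                                 base + rng.normal(0, 0.8, 3)))
    return pg.Structure(atoms, source="mini")


@pytest.fixture(scope="session")
def gate_pair():
    """Open-enriched and closed-enriched gate ensembles with truth."""
    p_open = pg.GateModelParams(seed=11, n_frames=251, open_fraction=0.8)
    p_closed = pg.GateModelParams(seed=12, n_frames=251, open_fraction=0.2)
    t_open, truth_open = pg.generate_gate_trajectory(p_open)
    t_closed, truth_closed = pg.generate_gate_trajectory(p_closed)
    return (p_open, t_open, truth_open), (p_closed, t_closed, truth_closed)


def gate_pocket_spec(params):
    return pg.PocketSpec(
        [(np.zeros(3), params.cavity_radius)], grid_spacing=1.0,
        contiguity_seed=np.zeros(3))
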
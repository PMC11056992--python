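import numpy as np
import pytest

from amorphdyn import synth
from amorphdyn.structures import Atom, Configuration, Molecule


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def config_from_motifs(names, offset=60.0, box=120.0):
    """Assemble one configuration from motif recipes placed at a fixed offset
    (single motif) — helper for geometry-exact tests."""
    mols, mol_id = [], 0
    all_bonds = []
    shift = np.zeros(3)
    for name in names:
        coords, bonds, _ = synth._build_motif(name)
        ids = []
        for m in range(coords.shape[0]):
            atoms = [Atom(el, role, coords[m][j] + offset + shift)
                     for j, (el, role, _) in enumerate(synth._TEMPLATE)]
            mols.append(Molecule(mol_id, "S", atoms))
            ids.append(mol_id)
            mol_id += 1
        all_bonds += [(ids[a], ids[b]) for a, b in bonds]
        shift = shift + np.array([0.0, 0.0, 30.0])  # motifs well separated
    return Configuration(np.array([box, box, box * 4.0]), mols), all_bonds


@pytest.fixture
def single_motif_config():
    return lambda name: config_from_motifs([name])
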
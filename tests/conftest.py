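import pytest

import nifcompat as nc
from nifcompat.synthetic import ComplexSpec, make_toy_complex


def build_model(pdb_text, receptor_chains=("A", "B"), model_index=1):
    atoms = nc.parse_structure(pdb_text)[0]
    return nc.split_receptor_ligand(atoms, set(receptor_chains), model_index=model_index)


@pytest.fixture(scope="session")
def toy_complex():
    """One synthetic docked complex: R = 8.5 Å, 3 salt bridges, 2 decoys."""
    pdb_text, manifest = make_toy_complex(
        ComplexSpec(target_R=8.5, n_bridges=3, decoy_charged_pairs=2, seed=7)
    )
    return pdb_text, manifest


@pytest.fixture(scope="session")
def toy_model(toy_complex):
    return build_model(toy_complex[0])
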
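import numpy as np
import pytest

from pharmscreen import builtin_dual_model
from pharmscreen.perception import fixture_drugs, mol_from_smiles


@pytest.fixture(scope="session")
def model():
    return builtin_dual_model()


@pytest.fixture(scope="session")
def drugs():
    """The ten packaged drugs, embedded once per test session."""
    return fixture_drugs()


@pytest.fixture(scope="session")
def small_mols():
    """Tiny molecules with one embedded conformer, keyed by name."""
    return {
        name: mol_from_smiles(smi, name, n_confs=1)
        for name, smi in [
            ("benzene", "c1ccccc1"),
            ("methanol", "CO"),
            ("ethane", "CC"),
            ("ethanol", "CCO"),
            ("n-butane", "CCCC"),
            ("methane", "C"),
            ("acetic_acid", "CC(=O)O"),
            ("pyridine", "c1ccncc1"),
        ]
    }


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
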
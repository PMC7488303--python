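import numpy as np
import pytest

from tomopack.fixtures import SynthSpec, fixture_structure_library, synth_atom_cloud


def make_pdb_text(coords, record="ATOM"):
    """Minimal fixed-column PDB text with one record per coordinate."""
    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"{record:<6}{i:>5}  CA  ALA A{i:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def globular_cloud():
    return synth_atom_cloud(SynthSpec(shape="globular", n_atoms=5000, seed=11))


@pytest.fixture(scope="session")
def rod_cloud():
    return synth_atom_cloud(SynthSpec(shape="rod", n_atoms=15000, extent=200.0, seed=12))


@pytest.fixture(scope="session")
def small_library():
    """Five coarse-grained rigid fixture structures (packing scenes)."""
    return fixture_structure_library(n_rigid=5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
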
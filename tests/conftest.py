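import numpy as np
import pytest

from knotfold.conditions import Conditions


@pytest.fixture(scope="session")
def cond298() -> Conditions:
    return Conditions(temperature=298.0)


@pytest.fixture(scope="session")
def toy_sequence() -> str:
    # synthetic test sequence (not a natural protein), proline at position 20
    return "MAKVLETAQRGDFSKWLNEPHIGYTTSCV"


@pytest.fixture()
def toy_pdb(tmp_path):
    """Synthetic 20-residue single-chain PDB with a compact random walk."""
    rng = np.random.default_rng(1)
    pos = np.cumsum(rng.normal(0.0, 2.5, (20, 3)), axis=0) + 50.0
    lines = [
        "ATOM  %5d  CA  ALA A%4d    %8.3f%8.3f%8.3f  1.00  0.00           C"
        % (i + 1, i + 1, x, y, z)
        for i, (x, y, z) in enumerate(pos)
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path
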
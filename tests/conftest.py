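import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# Human p53 C-terminal construct: five tetramerization-domain residues
# (351-355) plus the regulatory domain through 393.
REG_SEQUENCE = "KDAQAGKEPGGSRAHSSHLKSKKGQSTSRHKKLMFKTEGPDSD"
FIRST_RESIDUE = 351
PHOSPHOSITES = (366, 371, 376, 377, 378, 387, 392)


@pytest.fixture(scope="session")
def reg_sequence():
    return REG_SEQUENCE


@pytest.fixture(scope="session")
def phosphosites():
    return PHOSPHOSITES


@pytest.fixture(scope="session")
def np_topology():
    from regscape.chem_topology import parse_sequence

    return parse_sequence(REG_SEQUENCE, FIRST_RESIDUE)


@pytest.fixture(scope="session")
def sp_topology():
    from regscape.chem_topology import parse_sequence

    return parse_sequence(REG_SEQUENCE, FIRST_RESIDUE, [392])


@pytest.fixture(scope="session")
def fp_topology():
    from regscape.chem_topology import parse_sequence

    return parse_sequence(REG_SEQUENCE, FIRST_RESIDUE, PHOSPHOSITES)


@pytest.fixture(scope="session")
def two_state_model():
    """Symmetric two-basin Markov dihedral model with lambda_2 = 0.8."""
    from regscape.synthetic import MarkovDihedralModel

    return MarkovDihedralModel(
        centers=((-75.0, 145.0), (-63.0, -43.0)),
        transition=((0.9, 0.1), (0.1, 0.9)),
        jitter_deg=8.0,
    )


@pytest.fixture(scope="session")
def helix_peptide():
    from regscape.synthetic import build_peptide

    return build_peptide("A" * 12, (-57.0, -47.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
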
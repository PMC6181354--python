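import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from domarch.seq_io import SeqRecord
from domarch.synthetic_data import FamilyConfig, generate_families, generate_helix_pdb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def family_full_signal():
    """3 architectures x 10 sequences, 120 columns, full conservation."""
    return generate_families(FamilyConfig(seed=7, conservation=1.0))


@pytest.fixture(scope="session")
def helix12(tmp_path_factory):
    text, truth = generate_helix_pdb(12)
    path = tmp_path_factory.mktemp("helix") / "helix.pdb"
    path.write_text(text)
    return path, truth


@pytest.fixture
def two_clade_alignment():
    """Two maximally separated clades; identical rows within each clade."""
    a_seq = "AAAAKKKKLLLLMMMM" * 4
    b_seq = "WWWWFFFFYYYYPPPP" * 4
    return ([SeqRecord(id=f"a{i}", seq=a_seq) for i in range(4)]
            + [SeqRecord(id=f"b{i}", seq=b_seq) for i in range(4)])
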
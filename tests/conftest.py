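import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def fastq_file(tmp_path):
    """Small plain-text FASTQ with known reads."""
    path = tmp_path / "reads.fastq"
    path.write_text(
        "@r1 some description\nACGT\n+\nIIII\n"
        "@r2\nACGTACGTAC\n+\n!!!!!!!!!!\n"
        "@r3\nNNNN\n+\n++++\n"
    )
    return path


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "asm.fasta"
    path.write_text(">c1 desc\nACGT\nACGT\n>c2\nTTTT\n")
    return path
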
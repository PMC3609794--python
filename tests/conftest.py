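import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20130327)


@pytest.fixture
def random_seq(rng):
    """Factory for random ACGT strings."""

    def make(length: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=length))

    return make


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing (id, seq) pairs to a FASTA file in tmp_path."""

    counter = [0]

    def make(entries, name=None):
        counter[0] += 1
        path = tmp_path / (name or f"f{counter[0]}.fa")
        with open(path, "w") as out:
            for ident, seq in entries:
                out.write(f">{ident}\n{seq}\n")
        return path

    return make
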
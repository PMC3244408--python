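import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")

from seedshift import (
    Alphabet,
    NucleotideSequence,
    SimulationConfig,
    TranscriptRecord,
    generate_expression,
    generate_transcriptome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20111221)


@pytest.fixture
def make_transcript():
    def _make(residues: str, tid: str = "t1", cds: tuple[int, int] | None = None):
        seq = NucleotideSequence(residues, Alphabet.RNA)
        if cds is None:
            return TranscriptRecord(tid, seq)
        return TranscriptRecord(tid, seq, cds[0], cds[1])

    return _make


@pytest.fixture(scope="session")
def small_simulation():
    """One modest simulated screen shared by read-only tests."""
    config = SimulationConfig(n_transcripts=1200, rng_seed=11)
    records, regions, truth = generate_transcriptome(config)
    expression = generate_expression(truth, config)
    return config, records, regions, truth, expression
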
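import numpy as np
import pytest

from seppipe.sepdb import OrfConfig, Transcript, build_database
from seppipe.simdata import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_transcript(rng, length, tid="T1"):
    return Transcript(tid, "".join("ACGT"[i] for i in rng.integers(0, 4, size=length)))


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One default synthetic dataset shared by integration-style tests."""
    outdir = tmp_path_factory.mktemp("sim") / "run1"
    cfg = SimConfig(seed=1)
    truth = simulate_dataset(cfg, outdir)
    return cfg, outdir, truth


@pytest.fixture(scope="session")
def sim_db(sim_dataset):
    from seppipe.sepdb import read_transcripts

    _, outdir, _ = sim_dataset
    return build_database(read_transcripts(str(outdir / "transcripts.fasta")))
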
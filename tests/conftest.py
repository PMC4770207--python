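import pytest

from ribodesign.model import (CoreTemplate, DesignParams, Environment,
                              TargetTranscript)


@pytest.fixture(scope="session")
def core():
    return CoreTemplate.for_model("minimal")


@pytest.fixture(scope="session")
def env():
    """Standard physiological-ish environment (frozen, safe to share)."""
    return Environment(temperature=37.0, na_mM=100.0, mg_mM=0.1,
                       oligo_nM=500.0)


@pytest.fixture(scope="session")
def cold_env():
    """Cold, high-salt annealing environment: the Tm acceptance window then
    admits short GC-rich arms, so small hand-built scenarios lose nothing to
    the temperature filter."""
    return Environment(temperature=2.0, na_mM=1000.0, mg_mM=0.0,
                       oligo_nM=500.0)


@pytest.fixture(scope="session")
def gc_target():
    """32-nt hand-built target: two interior GUC sites in GC-only flanks
    (no accidental GUC possible — the only Us are the planted ones)."""
    seq = "GGCGGCCG" + "GUC" + "GCGGCCGGCG" + "GUC" + "CGGCCGCG"
    return TargetTranscript(id="gc2", sequence=seq)


@pytest.fixture
def small_params():
    return DesignParams(cut_triplets=frozenset({"GUC"}), arm_min=4, arm_max=5)
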
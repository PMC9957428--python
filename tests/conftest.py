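import numpy as np
import pytest

from mitocomp import SimSpec, load_tukubana_annotation, simulate_mitogenome


@pytest.fixture(scope="session")
def table2_genome():
    """The transcribed printed annotation (sequence-free)."""
    return load_tukubana_annotation()


@pytest.fixture(scope="session")
def table2_with_seq(table2_genome):
    """The printed annotation with a random sequence attached, so extraction
    arithmetic (overlaps, per-gene totals) can be exercised."""
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, table2_genome.length)])
    return table2_genome.with_sequence(seq)


@pytest.fixture(scope="session")
def sim_genome():
    """One simulated ground-pattern genome at default (reference) settings."""
    return simulate_mitogenome(SimSpec(seed=11))
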
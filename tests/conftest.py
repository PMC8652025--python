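import numpy as np
import pytest

from vss import SignalTrack, SimConfig, simulate_replicates


def make_track(chrom="chr21", starts=(0, 100), width=100, values=(5.0, 0.0)):
    starts = np.asarray(starts, dtype=np.int64)
    return SignalTrack.from_arrays(
        [chrom] * len(starts), starts, starts + width, values
    )


@pytest.fixture
def small_reps():
    """Two aligned 3-interval replicates on chr21."""
    t1 = make_track(values=(1.0, 2.0), starts=(0, 100))
    t2 = make_track(values=(4.0, 5.0), starts=(0, 100))
    from vss import align_replicates

    return align_replicates([t1, t2], "raw")


@pytest.fixture(scope="session")
def nb_simulation():
    """A moderate negative-binomial simulation shared across tests."""
    config = SimConfig(n_positions=20_000, seed=11)
    return simulate_replicates(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
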
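import numpy as np
import pytest

from sweepint.params import SimParams
from sweepint.sim import MutationRecord, init_population


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_single_locus_state(N, s, p0_freq, rng, R=1.0, position=0.5):
    """Population with one segregating mutation at a given frequency."""
    params = SimParams(N=N, U=0.0, R=R, s=s, generations=1, seed=0)
    state = init_population(params)
    state.rng = rng
    count = int(round(N * p0_freq))
    state.genotypes = np.zeros((N, 1), dtype=bool)
    state.genotypes[:count, 0] = True
    state.positions = np.array([position])
    state.s_values = np.array([s])
    state.col_ids = np.array([0], dtype=np.int64)
    state.registry = {0: MutationRecord(id=0, position=position, s=s, t_origin=0, count=count)}
    state.next_id = 1
    return state
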
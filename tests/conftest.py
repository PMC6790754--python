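import numpy as np
import pytest

from protodogma import Params, init_world


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small but dynamically alive world: 10 cells of 20 replicators."""
    return Params(V=20, m=0.1, delta_mut=0.05, t_max=50, init_cells=10,
                  n_tot=200, seed=7, record_every=10)


@pytest.fixture
def small_world(small_params):
    return init_world(small_params, np.random.default_rng(small_params.seed))


def make_single_cell_world(n_reps, k_value=1.0, substrate=0, rtype=None,
                           params=None, seed=0):
    """World with one protocell, for exercising per-cell chemistry."""
    from protodogma.world import World

    if params is None:
        params = Params(V=10 ** 9, m=0.0, d=0.02, n_tot=n_reps + substrate,
                        init_cells=1, seed=seed)
    w = World(params, np.random.default_rng(seed))
    w.cell_uid = np.array([0], dtype=np.int64)
    w.substrate = np.array([substrate], dtype=np.int64)
    w.next_cell_uid = 1
    w.rep_id = np.arange(n_reps, dtype=np.int64)
    w.next_rep_id = n_reps
    w.cell_ix = np.zeros(n_reps, dtype=np.int32)
    w.birth_step = np.zeros(n_reps, dtype=np.int32)
    if rtype is None:
        w.rtype = (np.arange(n_reps) % 2).astype(np.int8)
    else:
        w.rtype = np.asarray(rtype, dtype=np.int8)
    w.profile = np.full((n_reps, 8), k_value, dtype=np.float64)
    return w
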
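import itertools

import numpy as np
import pytest

import minarg as m

GRID = [(K, M) for K in (2, 3, 4, 6) for M in (1, 2, 3, 4)]
N_POP = 50.0
RHO_J = 0.005  # per-junction, per-generation recombination probability
THETA = 0.02  # mutations per tree per lineage per generation


def grid_config(K, M, **kw):
    params = dict(
        K=K, N=N_POP, M=M, junction_recomb_probs=RHO_J, mutation_rate=THETA
    )
    params.update(kw)
    return m.SimConfig(**params)


@pytest.fixture(scope="session")
def fig2():
    return m.fig2_fixture()


@pytest.fixture(scope="session")
def small_args():
    """100 small random ARGs (K<=4, M<=3, <=12 vertices) with mutations,
    half of them guaranteed to contain a non-t-coalescent coalescence."""
    out = []
    for seed in range(100):
        K = 2 + seed % 3
        M = 1 + seed % 3
        out.append(
            m.random_small_arg(
                K=K,
                M=M,
                max_vertices=12,
                seed=seed,
                require_non_t_coalescent=(M > 1 and seed % 2 == 0),
            )
        )
    return out


@pytest.fixture(scope="session")
def grid_std():
    """200 standard binary ARGs over the (K, M) grid at N=50, annotated."""
    out = []
    n = 0
    for K, M in GRID:
        for r in range(13):
            if n >= 200:
                break
            n += 1
            cfg = grid_config(K, M)
            rng = np.random.default_rng([42, K, M, r])
            out.append(m.annotate_mutations(m.simulate_binary_arg(cfg, rng), cfg, rng))
    return out


@pytest.fixture(scope="session")
def grid_std_mds(grid_std):
    return [m.minimal_descriptor(a) for a in grid_std]


@pytest.fixture(scope="session")
def grid_md_direct():
    """200 directly sampled binary minimal descriptors over the same grid."""
    out = []
    n = 0
    for K, M in GRID:
        for r in range(13):
            if n >= 200:
                break
            n += 1
            cfg = grid_config(K, M, mutation_rate=0.0)
            out.append(m.simulate_md_direct(cfg, np.random.default_rng([77, K, M, r])))
    return out
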
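import numpy as np
import pytest

import lncwalk as lw
from lncwalk.simulate import to_pipeline_inputs


@pytest.fixture
def toy_expression():
    rng = np.random.default_rng(7)
    return lw.ExpressionProfiles(
        entity_ids=["e1", "e2", "e3", "e4"],
        condition_ids=[f"c{k}" for k in range(6)],
        values=rng.standard_normal((4, 6)),
    )


@pytest.fixture
def toy_annotations():
    return lw.AnnotationTable(
        {
            "p1": {"GO:0000001", "GO:0000002"},
            "p2": {"GO:0000001"},
            "p3": {"GO:0000003"},
        }
    )


def random_walk_instance(rng, u, v):
    """A random normalized problem (L_N, P_N, A) with nonzero A."""
    L = rng.random((u, u))
    L = np.triu(L, 1)
    L = L + L.T
    P = rng.random((v, v))
    P = np.triu(P, 1)
    P = P + P.T
    A = (rng.random((u, v)) < 0.4).astype(float)
    if not A.any():
        A[rng.integers(u), rng.integers(v)] = 1.0
    L_N = lw.laplacian_normalize(lw.SimilarityNet(
        [f"l{i}" for i in range(u)], np.clip(L, 0, 1)))
    P_N = lw.laplacian_normalize(lw.PartnerNet([f"p{j}" for j in range(v)], P))
    assoc = lw.AssocMatrix([f"l{i}" for i in range(u)], [f"p{j}" for j in range(v)], A)
    return L_N, P_N, assoc


@pytest.fixture(scope="session")
def synth_batch():
    """Twenty synthetic datasets at the generator's default settings,
    shared by the recovery and ablation studies."""
    out = []
    for seed in range(20):
        ds = lw.generate(lw.SynthConfig(seed=seed))
        out.append((seed, ds, to_pipeline_inputs(ds)))
    return out
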
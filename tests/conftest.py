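import numpy as np
import pandas as pd
import pytest

from groupconn.cohort import SubjectCohort
from groupconn.synthetic import SyntheticConfig, generate_cohort, reference_configs


def make_nodes(coords, hemispheres, systems=None, names=None):
    coords = np.asarray(coords, dtype=float)
    df = pd.DataFrame(
        {
            "name": names or [f"n{i}" for i in range(len(coords))],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "hemisphere": list(hemispheres),
        }
    )
    if systems is not None:
        df["system"] = list(systems)
    return df


def cohort_from_edges(coords, hemispheres, subject_edge_weights, systems=None):
    """Build a cohort from per-subject {(i, j): weight} dicts."""
    n = len(coords)
    mats = []
    for edges in subject_edge_weights:
        a = np.zeros((n, n))
        for (i, j), w in edges.items():
            a[i, j] = a[j, i] = w
        mats.append(a)
    nodes = make_nodes(coords, hemispheres, systems)
    ids = tuple(f"sub-{s}" for s in range(len(mats)))
    return SubjectCohort(np.stack(mats), nodes, ids)


@pytest.fixture
def collinear_cohort():
    """Four collinear nodes at x = 0, 1, 3, 7; three subjects.

    Pair lengths: ab=1, bc=2, ac=3, cd=4, bd=6, ad=7.  Subject edge sets
    {(a,b),(a,d)}, {(a,b),(c,d)}, {(b,c),(a,d)}.
    """
    coords = [(0, 0, 0), (1, 0, 0), (3, 0, 0), (7, 0, 0)]
    subjects = [
        {(0, 1): 1.0, (0, 3): 2.0},
        {(0, 1): 3.0, (2, 3): 1.0},
        {(1, 2): 2.0, (0, 3): 4.0},
    ]
    return cohort_from_edges(coords, "LLLL", subjects)


@pytest.fixture(scope="session")
def default_cohorts():
    """20 seeded cohorts at the default synthetic conditions, with the
    distance, tau_avg, and simple group networks prebuilt."""
    from groupconn.builders import build_group_network
    from groupconn.cohort import euclidean_distances

    cfg = reference_configs()["default"]
    out = []
    for s in range(20):
        cohort = generate_cohort(cfg, seed=1000 + s)
        dist = euclidean_distances(cohort.nodes)
        nets = {
            m: build_group_network(m, cohort, dist=dist)
            for m in ("distance", "tau_avg", "simple")
        }
        out.append((cohort, dist, nets))
    return out


@pytest.fixture(scope="session")
def identical_cohort():
    """T=5 identical subjects drawn once from the small synthetic config
    (N=60, generic coordinates give distinct edge lengths)."""
    cfg = reference_configs()["small"]
    base = generate_cohort(cfg, seed=7)
    mats = np.repeat(base.matrices[:1], 5, axis=0)
    return SubjectCohort(mats, base.nodes, tuple(f"sub-{s}" for s in range(5)))
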
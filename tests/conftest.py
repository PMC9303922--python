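import numpy as np
import pytest

import nbsfc

BASE_SEED = 20260929


def brute_force_components(edges):
    """Oracle: transitive closure over nodes, then partition of the edges."""
    nodes = sorted({n for e in edges for n in e})
    reach = {n: {n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for i, j in edges:
            merged = reach[i] | reach[j]
            for n in merged:
                if reach[n] != merged:
                    reach[n] = merged
                    changed = True
            reach[i] = reach[j] = merged
    groups = {}
    for i, j in edges:
        key = frozenset(reach[i])
        groups.setdefault(key, set()).add((min(i, j), max(i, j)))
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


@pytest.fixture(scope="session")
def two_cond_design():
    return nbsfc.generate_design(
        12, ["self", "stranger"], tr=2.0, isi_range=(2.0, 6.0), seed=101
    )


@pytest.fixture(scope="session")
def star_effect():
    return nbsfc.GroundTruthEffect(
        edge_set=[(0, 1), (0, 2), (0, 3), (0, 4)],
        condition_deltas={"self": 0.28},
        baseline_corr=0.1,
    )


@pytest.fixture(scope="session")
def small_cohort_z(two_cond_design, star_effect):
    """Fisher-z stacks for a small effect cohort, shared across GLM/NBS tests."""
    cohort = nbsfc.generate_cohort(
        20,
        dict(
            n_trials_per_condition=24,
            conditions=["self", "stranger"],
            tr=2.0,
            isi_range=(2.0, 6.0),
            n_runs=1,
        ),
        star_effect,
        between_subject_sd=0.05,
        seed=BASE_SEED,
    )
    rrc = [
        nbsfc.build_rrc(
            nbsfc.preprocess_subject(s), s.design, ["self", "stranger"]
        )
        for s in cohort.subjects
    ]
    return nbsfc.stack_cohort_z(rrc, ["self", "stranger"])
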
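import numpy as np
import pytest

import synconn as sc
from synconn._seeds import child_int_seed


@pytest.fixture(scope="session")
def small_cohort():
    """A 48-node functional cohort used by several module tests."""
    cfg = sc.CohortConfig(n_per_group=12, n_nodes=48, seed=11)
    cohort = sc.generate_functional_cohort(cfg)
    cohort.functional = [
        sc.build_functional_matrix(ts, subject_id=sid)
        for ts, sid in zip(cohort.timeseries, cohort.subject_ids)
    ]
    return cohort


@pytest.fixture(scope="session")
def scaled_cohort_curves():
    """Metric curves for a reduced synthetic cohort over the functional grid.

    Shared by the sparsity-summary and small-world acceptance checks (the
    expensive part is the rewired-null ensembles).
    """
    cfg = sc.CohortConfig(n_per_group=8, n_nodes=128, seed=5)
    cohort = sc.generate_functional_cohort(cfg)
    weights = [sc.build_functional_matrix(ts).weights for ts in cohort.timeseries]
    grid = sc.default_functional_grid()
    curves = [
        sc.metric_curve(
            w, grid=grid, n_nulls=10, n_louvain=10, seed=child_int_seed(5, f"curve-{i}")
        )
        for i, w in enumerate(weights)
    ]
    return cohort, curves
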
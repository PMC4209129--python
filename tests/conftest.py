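"""Shared fixtures: reference parameters, synthetic cohorts, simulations.

The expensive objects (cohorts, the starvation sweep) are session-scoped
and generated programmatically — nothing is read from disk.
"""

import numpy as np
import pytest

from cognatebias import (
    DEFAULT_PARAMS,
    SyntheticCohortConfig,
    bias_table,
    make_cohort_records,
    simulate_starvation,
)

#: cognate counts of the critical enzyme swept in the dynamic analyses
SWEEP_N = (12, 16, 20, 24, 28, 32, 36)

#: study conditions of the bias-recovery cohort: 200 organisms, 200 bulk
#: proteins each, injected enzyme shifts of -3 (Trp), 0 (Ala, implicit)
#: and +3 (Arg) residues
RECOVERY_SEED = 20201
RECOVERY_DELTAS = {"W": -3.0, "R": 3.0}

#: two environment groups with opposite bias profiles, 50 organisms each
TWO_GROUP_SEED = 777
TWO_GROUP_SHIFT = 6.0


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def recovery_cohort():
    config = SyntheticCohortConfig(
        seed=RECOVERY_SEED, n_organisms=200, proteins_per_organism=200,
        group_deltas=(dict(RECOVERY_DELTAS),))
    proteomes, annotations, truth = make_cohort_records(config)
    table = bias_table(proteomes, annotations)
    return {"config": config, "proteomes": proteomes,
            "annotations": annotations, "truth": truth, "table": table}


@pytest.fixture(scope="session")
def two_group_cohort():
    low = {aa: -TWO_GROUP_SHIFT for aa in "ACDEFGHIKLMNPQRSTVWY"}
    high = {aa: TWO_GROUP_SHIFT for aa in "ACDEFGHIKLMNPQRSTVWY"}
    config = SyntheticCohortConfig(
        seed=TWO_GROUP_SEED, n_organisms=100, proteins_per_organism=200,
        group_deltas=(low, high))
    proteomes, annotations, truth = make_cohort_records(config)
    table = bias_table(proteomes, annotations)
    groups = np.array([config.group_of(i) for i in range(config.n_organisms)])
    return {"config": config, "table": table, "groups": groups}


@pytest.fixture(scope="session")
def starvation_sweep(params):
    return {n: simulate_starvation(params.with_n(n)) for n in SWEEP_N}
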
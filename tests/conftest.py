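"""Shared fixtures: a toy genome for exact arithmetic checks and a
desk-scale simulated cohort reused by the integration-level tests."""

import numpy as np
import pytest

import embryort as ert
from embryort.qc import qc_cells


@pytest.fixture(scope="session")
def toy_bins():
    """One 1 Mb chromosome at 100 kb bins; no masked bins."""
    return ert.partition_genome({"c1": 1_000_000}, 100_000)


@pytest.fixture(scope="session")
def desk_bins():
    """Default 2 x 100 Mb genome at 100 kb bins with synthetic GC."""
    return ert.default_genome(seed=7)


@pytest.fixture(scope="session")
def rt_truth(desk_bins):
    return ert.make_rt_truth(desk_bins, correlation_length_bins=20, coupling=2.0, seed=7)


@pytest.fixture(scope="session")
def cohort(rt_truth):
    """150 S + 30 G1 cells at the default depth and noise settings."""
    return ert.simulate_cells(
        rt_truth, n_g1=30, n_s=150, flip_rate=0.02, gc_coeff=0.3, seed=8
    )


@pytest.fixture(scope="session")
def reference_cohort(rt_truth):
    """Dedicated non-replicating reference cells (G1 ES-cell analogue)."""
    return ert.simulate_cells(
        rt_truth, n_g1=30, n_s=0, flip_rate=0.0, gc_coeff=0.3, seed=9
    )


@pytest.fixture(scope="session")
def cohort_profiles(cohort, reference_cohort, desk_bins):
    return qc_cells(
        cohort.counts, cohort.cell_ids, desk_bins,
        reference_counts=reference_cohort.counts,
    )
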
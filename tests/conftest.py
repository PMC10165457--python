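import numpy as np
import pytest

from phosphodia import (
    MarkerSpec,
    SimulationConfig,
    build_staggered_scheme,
    class1_filter,
    collapse_to_sites,
    log2_transform,
    qc_floor,
    sample_normality_gate,
    simulate_report,
)


@pytest.fixture(scope="session")
def small_scheme():
    """Staggered scheme with 10 windows per phase (20 effective windows)."""
    return build_staggered_scheme(500.0, 540.0, 4.0)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but structurally complete simulation: 4 groups of 8, planted
    markers in each non-control group."""
    return SimulationConfig(
        n_sites=300,
        n_samples_per_group=8,
        markers={
            "CKD": MarkerSpec(5, 1.5),
            "low_grade": MarkerSpec(5, 1.5),
            "high_grade": MarkerSpec(5, 1.5),
        },
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_report(tiny_config):
    return simulate_report(tiny_config)


@pytest.fixture(scope="session")
def gated_tiny_table(tiny_report):
    """Class-1 filtered, rolled-up, floored, log2, normality-gated table."""
    records, truth = tiny_report
    table = collapse_to_sites(
        class1_filter(records, 0.75), groups=truth.sample_groups
    )
    table = qc_floor(table)
    table = log2_transform(table)
    table, _ = sample_normality_gate(table)
    return table


def assert_records_equal(a, b):
    """Record equality with NaN-tolerant abundance comparison."""
    assert len(a) == len(b)
    key = lambda r: (r.protein_accession, r.modified_sequence, r.charge)
    for ra, rb in zip(sorted(a, key=key), sorted(b, key=key)):
        assert ra.modified_sequence == rb.modified_sequence
        assert ra.protein_accession == rb.protein_accession
        assert ra.other_accessions == rb.other_accessions
        assert ra.charge == rb.charge
        assert ra.sites == rb.sites
        assert set(ra.abundances) == set(rb.abundances)
        for s, va in ra.abundances.items():
            vb = rb.abundances[s]
            assert (np.isnan(va) and np.isnan(vb)) or va == vb
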
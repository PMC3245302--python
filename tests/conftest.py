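import pytest

import dermadup as dd


@pytest.fixture(scope="session")
def ref():
    return dd.build_reference()


@pytest.fixture(scope="session")
def allele(ref):
    return dd.build_fm_allele(ref, "FM_2")


@pytest.fixture(scope="session")
def cohort(ref, allele):
    """Default study-scale array cohort (12 FM / 3 het / 12 WT, seed 1)."""
    return dd.simulate_array_cohort(ref, allele, dd.ArrayCohortSpec(seed=1))


@pytest.fixture(scope="session")
def small_pools(ref, allele):
    """Locus-only pools at reduced depth for unit-level checks."""
    fm = dd.simulate_matepair_pool(
        ref, allele, dd.PoolSpec(seed=11, target_depth=8, region_only=True, genotype="FM/FM")
    )
    wt = dd.simulate_matepair_pool(
        ref, None, dd.PoolSpec(seed=12, target_depth=8, region_only=True)
    )
    return fm, wt


@pytest.fixture(scope="session")
def full_pools(ref, allele):
    """Study-scale pools: 30x, 2.5 kb inserts, locus embedded in the toy
    chromosome (library totals are chromosome-wide, as in real mapping)."""
    fm = dd.simulate_matepair_pool(ref, allele, dd.PoolSpec(seed=1, genotype="FM/FM"))
    wt = dd.simulate_matepair_pool(ref, None, dd.PoolSpec(seed=2))
    return fm, wt


@pytest.fixture(scope="session")
def block_lengths(ref):
    return {name: iv.length for name, iv in ref.blocks.items()}
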
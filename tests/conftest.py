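import numpy as np
import pytest

from bsakit import (
    FilterConfig,
    SimParams,
    SnpProfile,
    SnpRecord,
    identify_candidates,
    simulate_scenario,
)

SMALL_PARAMS = SimParams(
    genome_length=20_000,
    n_chromosomes=2,
    n_genes=2,
    cds_length=600,
    n_exons=2,
    intron_length=80,
    n_induced_snps=20,
    n_artifact_snps=30,
    n_lines=3,
    seed=11,
)


@pytest.fixture(scope="session")
def small_params():
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def small_genome(small_params):
    from bsakit import simulate_genome

    return simulate_genome(small_params)


@pytest.fixture(scope="session")
def default_scenario():
    """The full study conditions: 5 lines, 455 F2, pool of 96, 100x depth."""
    return simulate_scenario(SimParams())


@pytest.fixture(scope="session")
def default_report(default_scenario):
    sc = default_scenario
    return identify_candidates(
        sc.focal_profile, sc.other_profiles, FilterConfig(), genome=sc.genome
    )


def make_profile(line_id, records):
    """Build a profile from (chrom, pos, ref, alt, alt_count, depth) tuples."""
    return SnpProfile(line_id, [SnpRecord(*r) for r in records])


def random_profile(rng, line_id, n, n_positions=500):
    """Random profile with the frequency/depth mix the filters act on."""
    records = {}
    while len(records) < n:
        chrom = f"chr{rng.integers(1, 3)}"
        pos = int(rng.integers(1, n_positions + 1))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        depth = int(rng.integers(1, 400))
        alt_count = int(rng.integers(0, depth + 1))
        rec = SnpRecord(chrom, pos, str(ref), str(alt), alt_count, depth)
        records.setdefault(rec.key, rec)
    return SnpProfile(line_id, records.values())
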
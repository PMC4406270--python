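import numpy as np
import pytest

from clinescan import (
    Colony,
    GenotypeDataset,
    Locus,
    SyntheticTruth,
    simulate_transect,
)

try:  # derandomise hypothesis when available
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci", derandomize=True, deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:
    pass


def make_dataset(colony_genotypes, ploidy=2, positions=None, haplotypes=None):
    """Build a GenotypeDataset from nested allele-label lists.

    ``colony_genotypes``: per colony, per individual, per locus, a tuple
    of allele labels (len == ploidy) or None for missing.
    """
    n_loci = len(colony_genotypes[0][0])
    labels = [set() for _ in range(n_loci)]
    for col in colony_genotypes:
        for ind in col:
            for li, g in enumerate(ind):
                if g is not None:
                    labels[li].update(g)
    loci = [
        Locus(f"L{li + 1}", ploidy, tuple(sorted(labels[li])) or (1,))
        for li in range(n_loci)
    ]
    if positions is None:
        positions = list(range(len(colony_genotypes)))
    colonies = [Colony(f"c{ci + 1}", float(positions[ci])) for ci in range(len(colony_genotypes))]
    colony_of = []
    flat = []
    for ci, col in enumerate(colony_genotypes):
        for ind in col:
            colony_of.append(ci)
            flat.append(ind)
    calls = []
    for li, locus in enumerate(loci):
        code = {lab: k for k, lab in enumerate(locus.alleles)}
        arr = np.full((len(flat), ploidy), -1, dtype=np.int32)
        for r, ind in enumerate(flat):
            if ind[li] is not None:
                arr[r] = [code[a] for a in ind[li]]
        calls.append(arr)
    return GenotypeDataset(loci, colonies, calls, np.array(colony_of))


@pytest.fixture(scope="session")
def small_transect():
    """A modest simulated transect reused by read-only tests."""
    truth = SyntheticTruth(
        n_colonies=8, n_per_colony=20, n_micro_loci=6, n_haplotypes=6, seed=42
    )
    return simulate_transect(truth)


@pytest.fixture
def two_pool_blocks():
    """Two colonies drawn from strongly diverged pools, no cline."""
    truth = SyntheticTruth(
        n_colonies=2, n_per_colony=50, width_km=1e-3, center_km=1500.0,
        transect_km=3000.0, n_micro_loci=12, pool_divergence_fst=0.3,
        drift_fst=0.0, seed=7,
    )
    return simulate_transect(truth)
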
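"""Shared fixtures: compact synthetic cohorts generated at test time."""

import numpy as np
import pytest

import jointgt as jg


@pytest.fixture(scope="session")
def small_panel():
    return jg.simdata.simulate_panel(
        n_founders=6,
        n_haplotypes=100,
        n_snps=100,
        recomb_prob=0.02,
        mutation_prob=0.001,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_truth(small_panel):
    return jg.simdata.simulate_cohort(small_panel, n_samples=50, seed=2)


@pytest.fixture(scope="session")
def small_pileups(small_truth):
    return jg.simdata.simulate_reads(
        small_truth,
        mean_coverage=2.0,
        read_error=0.001,
        fragment_error=1e-4,
        overlap_fraction=0.3,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_intensities(small_truth):
    return jg.simdata.simulate_intensities(small_truth, seed=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pileup(rng, n_fragments=4, overlap_prob=0.5, ref="A", alt="G"):
    """A random pileup over all four bases for oracle comparisons."""
    bases = list(jg.BASES)
    frags = []
    for k in range(n_fragments):
        n_obs = 2 if rng.random() < overlap_prob else 1
        obs = [
            (bases[rng.integers(0, 4)], int(rng.integers(5, 41)))
            for _ in range(n_obs)
        ]
        frags.append(jg.FragmentObservation(f"f{k}", obs))
    return jg.SitePileup("snp0", "s0", ref, alt, frags)
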
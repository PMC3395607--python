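"""Fragment-aware and read-independent genotype likelihoods vs oracles."""

import itertools

import numpy as np
import pytest

import jointgt as jg
from jointgt import seqlik
from jointgt.containers import BASES


def oracle_base_lik(b, q, h):
    e = 10 ** (-q / 10)
    return 1 - e if b == h else e / 3


def oracle_fragment_likelihood(frag, alleles, p):
    """Exhaustive enumeration over (haplotype, fragment-base) states."""
    total = 0.0
    for h in alleles:
        for f in BASES:
            pf = (1 - p) if f == h else p / 3
            term = pf
            for b, q in frag.observations:
                term *= oracle_base_lik(b, q, f)
            total += 0.5 * term
    return total


def oracle_read_likelihood(pileup, alleles):
    prod = 1.0
    for frag in pileup.fragments:
        for b, q in frag.observations:
            prod *= 0.5 * (oracle_base_lik(b, q, alleles[0]) + oracle_base_lik(b, q, alleles[1]))
    return prod


class TestBaseObsLikelihood:
    def test_match_and_mismatch_formulas(self):
        assert seqlik.base_obs_likelihood("A", 30, "A") == pytest.approx(0.999)
        assert seqlik.base_obs_likelihood("C", 30, "A") == pytest.approx(0.001 / 3)

    def test_sums_to_one_over_observed_bases(self):
        # enumeration oracle: the four observation probabilities partition
        for h in BASES:
            for q in (0, 7, 13, 30, 60):
                total = sum(seqlik.base_obs_likelihood(b, q, h) for b in BASES)
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            seqlik.base_obs_likelihood("N", 30, "A")


class TestFragmentLikelihood:
    def test_p0_homozygous_reduces_to_read_product(self):
        frag = jg.FragmentObservation("f", [("A", 25), ("A", 31)])
        lik = seqlik.fragment_genotype_likelihood(frag, ("A", "A"), fragment_error=0.0)
        expected = oracle_base_lik("A", 25, "A") * oracle_base_lik("A", 31, "A")
        assert lik == pytest.approx(expected, rel=1e-14)

    def test_matches_enumeration_oracle_on_random_fragments(self, rng):
        for _ in range(1000):
            n_obs = int(rng.integers(1, 3))
            frag = jg.FragmentObservation(
                "f",
                [(BASES[rng.integers(0, 4)], int(rng.integers(2, 41)))
                 for _ in range(n_obs)],
            )
            alleles = tuple(rng.choice(list(BASES), size=2, replace=False))
            p = float(rng.choice([0.0, 1e-4, 1e-2, 0.3]))
            got = seqlik.fragment_genotype_likelihood(frag, alleles, p)
            want = oracle_fragment_likelihood(frag, alleles, p)
            assert got == pytest.approx(want, rel=1e-14)

    def test_overlapping_error_pair_less_damning_than_read_model(self):
        # two alt-base mates on a hom-ref genotype: the fragment model
        # explains them as one library-prep error, the read model as two
        # independent sequencing errors
        frag = jg.FragmentObservation("f", [("G", 30), ("G", 30)])
        p = 1e-4
        frag_lik = seqlik.fragment_genotype_likelihood(frag, ("A", "A"), p)
        pile = jg.SitePileup("s", "x", "A", "G", [frag])
        read_lik = seqlik.read_independent_genotype_likelihood(pile, ("A", "A"))
        assert frag_lik > read_lik
        # the factor matches the enumeration oracle exactly
        want = oracle_fragment_likelihood(frag, ("A", "A"), p)
        assert frag_lik / read_lik == pytest.approx(
            want / oracle_read_likelihood(pile, ("A", "A")), rel=1e-12
        )
        # the confidence gap is large (orders of magnitude, per the ~1e-4
        # fragment error rate)
        assert frag_lik / read_lik > 50


class TestReadIndependentLikelihood:
    def test_empty_pileup_is_one(self):
        pile = jg.SitePileup("s", "x", "A", "G", [])
        for alleles in (("A", "A"), ("A", "G"), ("G", "G")):
            assert seqlik.read_independent_genotype_likelihood(pile, alleles) == 1.0

    def test_single_matching_read(self):
        pile = jg.SitePileup(
            "s", "x", "A", "G", [jg.FragmentObservation("f", [("A", 20)])]
        )
        assert seqlik.read_independent_genotype_likelihood(pile, ("A", "A")) == pytest.approx(0.99)

    def test_matches_loop_oracle_on_random_pileups(self, rng):
        from conftest import random_pileup

        for _ in range(50):
            pile = random_pileup(rng, n_fragments=int(rng.integers(1, 6)))
            for alleles in (("A", "A"), ("A", "G"), ("G", "G")):
                got = seqlik.read_independent_genotype_likelihood(pile, alleles)
                assert got == pytest.approx(oracle_read_likelihood(pile, alleles), rel=1e-12)


class TestSiteGenotypeLikelihoods:
    def test_empty_pileup_flat(self):
        pile = jg.SitePileup("s", "x", "A", "G", [])
        np.testing.assert_array_equal(
            seqlik.site_genotype_likelihoods(pile), np.ones(3)
        )

    def test_fragment_equals_read_for_hom_at_p0_no_overlap(self, rng):
        from conftest import random_pileup

        for _ in range(20):
            pile = random_pileup(rng, n_fragments=3, overlap_prob=0.0)
            f = seqlik.site_genotype_likelihoods(pile, fragment_error=0.0, mode="fragment")
            r = seqlik.site_genotype_likelihoods(pile, fragment_error=0.0, mode="read")
            # homozygous entries agree exactly (bitwise up to normalisation)
            assert f[0] / f.max() == pytest.approx(r[0] / r.max(), rel=1e-12)
            assert f[2] / f.max() == pytest.approx(r[2] / r.max(), rel=1e-12)

    def test_matches_product_of_fragment_oracle(self, rng):
        from conftest import random_pileup

        p = 1e-3
        for _ in range(30):
            pile = random_pileup(rng, n_fragments=int(rng.integers(1, 5)))
            got = seqlik.site_genotype_likelihoods(pile, fragment_error=p)
            raw = []
            for alleles in (("A", "A"), ("A", "G"), ("G", "G")):
                prod = 1.0
                for frag in pile.fragments:
                    prod *= oracle_fragment_likelihood(frag, alleles, p)
                raw.append(prod)
            want = np.asarray(raw) / max(raw)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_invalid_mode_rejected(self):
        pile = jg.SitePileup("s", "x", "A", "G", [])
        with pytest.raises(ValueError):
            seqlik.site_genotype_likelihoods(pile, mode="bogus")


class TestBatchPath:
    def test_batch_matches_scalar(self, small_pileups):
        batch = seqlik.pileup_log_likelihood_matrix(small_pileups, fragment_error=1e-4)
        for key in list(small_pileups.pileups)[:300]:
            trip = seqlik.site_genotype_likelihoods(
                small_pileups.pileups[key], fragment_error=1e-4
            )
            np.testing.assert_allclose(
                np.exp(batch[key]), trip, rtol=1e-10,
                err_msg=f"batch/scalar mismatch at {key}",
            )

    def test_batch_read_mode_matches_scalar(self, small_pileups):
        batch = seqlik.pileup_log_likelihood_matrix(small_pileups, mode="read")
        for key in list(small_pileups.pileups)[:200]:
            trip = seqlik.site_genotype_likelihoods(
                small_pileups.pileups[key], mode="read"
            )
            np.testing.assert_allclose(np.exp(batch[key]), trip, rtol=1e-10)

    def test_no_coverage_entries_flat(self, small_pileups):
        batch = seqlik.pileup_log_likelihood_matrix(small_pileups)
        covered = set(small_pileups.pileups)
        S, N = len(small_pileups.snp_ids), len(small_pileups.sample_ids)
        uncovered = [
            (i, j) for i in range(0, S, 17) for j in range(0, N, 7)
            if (i, j) not in covered
        ]
        for key in uncovered:
            np.testing.assert_array_equal(batch[key], np.zeros(3))


class TestFragmentModelAdvantage:
    def test_true_genotype_likelihood_gap_grows_with_overlap(self, small_truth):
        # fragment-mode mean log-likelihood of the true genotype (raw, not
        # normalised) is >= the read-mode value, and the gap grows with
        # overlap_fraction: shared library-prep errors are counted once, and
        # the which-haplotype uncertainty of an overlapping pair is paid
        # once per fragment rather than once per read
        p = 1e-4
        gaps = []
        for ov in (0.0, 0.4, 0.8):
            deltas = []
            for seed in range(20):
                piles = jg.simdata.simulate_reads(
                    small_truth, mean_coverage=2.0, read_error=0.002,
                    fragment_error=p, overlap_fraction=ov, seed=500 + seed,
                )
                lf = lr = n = 0.0
                for (i, j), pile in piles.pileups.items():
                    g = int(small_truth.genotypes[i, j])
                    alleles = (
                        pile.ref_base if g < 2 else pile.alt_base,
                        pile.alt_base if g > 0 else pile.ref_base,
                    )
                    frag_l = 1.0
                    for frag in pile.fragments:
                        frag_l *= seqlik.fragment_genotype_likelihood(frag, alleles, p)
                    read_l = seqlik.read_independent_genotype_likelihood(pile, alleles)
                    lf += np.log(max(frag_l, 1e-300))
                    lr += np.log(max(read_l, 1e-300))
                    n += 1
                deltas.append((lf - lr) / n)
            gaps.append(np.mean(deltas))
        # at overlap 0 the two models coincide to order p, so the gap is
        # zero within that order; with overlap it must be positive
        assert gaps[2] >= gaps[1] >= gaps[0] >= -10 * p
        assert gaps[2] > 0

    def test_identical_when_no_overlap_and_p0(self, small_truth):
        piles = jg.simdata.simulate_reads(
            small_truth, mean_coverage=1.0, overlap_fraction=0.0, seed=77
        )
        fr = seqlik.pileup_log_likelihood_matrix(piles, 0.0, "fragment")
        rd = seqlik.pileup_log_likelihood_matrix(piles, 0.0, "read")
        np.testing.assert_allclose(fr, rd, atol=1e-9)

    def test_posterior_calibration_monotone(self, small_truth):
        # binned predicted posterior vs empirical concordance is monotone
        piles = jg.simdata.simulate_reads(
            small_truth, mean_coverage=2.0, overlap_fraction=0.5,
            fragment_error=1e-3, seed=88,
        )
        ll = seqlik.pileup_log_likelihood_matrix(piles, 1e-3, "fragment")
        lik = np.exp(ll)
        post = lik / lik.sum(axis=2, keepdims=True)
        pred = post.max(axis=2)
        correct = post.argmax(axis=2) == small_truth.genotypes
        bins = [(1 / 3, 0.8), (0.8, 0.95), (0.95, 1.0001)]
        rates = []
        for lo, hi in bins:
            sel = (pred >= lo) & (pred < hi)
            if sel.sum() > 50:
                rates.append(correct[sel].mean())
        assert all(a <= b + 0.02 for a, b in zip(rates, rates[1:]))


def _norm(ll):
    lik = np.exp(ll)
    return lik / lik.sum(axis=2, keepdims=True)
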
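"""Synthetic-data generator: copying model, reads, intensities, covariates."""

import numpy as np
import pytest
from scipy import stats

import jointgt as jg
from jointgt import simdata


def brute_force_r2(haps, i, j):
    """LD r^2 between two sites by direct haplotype counting."""
    a, b = haps[:, i].astype(float), haps[:, j].astype(float)
    pa, pb = a.mean(), b.mean()
    pab = (a * b).mean()
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        return np.nan
    return (pab - pa * pb) ** 2 / denom


class TestSimulatePanel:
    def test_degenerate_single_founder_no_noise_is_empty(self):
        # all haplotypes identical -> every column monomorphic -> dropped
        panel = simdata.simulate_panel(1, 5, 50, recomb_prob=0.0, mutation_prob=0.0, seed=0)
        assert panel.n_snps == 0

    def test_no_recombination_copies_a_founder(self):
        mut = 0.01
        panel = simdata.simulate_panel(2, 40, 300, recomb_prob=0.0, mutation_prob=mut, seed=7)
        # keep founder rows: they are the first two haplotypes (mutated copies)
        raw = simdata.simulate_panel(2, 2, 300, recomb_prob=0.0, mutation_prob=0.0, seed=7)
        founders = raw.haplotypes
        # every non-founder haplotype matches one founder at >= 1 - 3*mut of sites
        full = simdata.simulate_panel(2, 40, 300, recomb_prob=0.0, mutation_prob=mut, seed=7)
        # compare against both founder patterns on the shared polymorphic columns
        assert full.n_snps > 0
        for h in full.haplotypes:
            best = max(
                np.mean(h == f)
                for f in full.haplotypes[:2]  # founders survive as first rows
            )
            assert best >= 1 - 6 * mut

    def test_adjacent_ld_exceeds_distant_ld(self):
        adj, far = [], []
        for seed in range(20):
            panel = simdata.simulate_panel(5, 80, 120, recomb_prob=0.03,
                                           mutation_prob=0.002, seed=seed)
            haps = panel.haplotypes
            S = panel.n_snps
            for i in range(0, S - 1, 7):
                adj.append(brute_force_r2(haps, i, i + 1))
            for i in range(0, S - 51, 7):
                far.append(brute_force_r2(haps, i, i + 50))
        assert np.nanmean(adj) > np.nanmean(far)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simdata.simulate_panel(1, 5, 0, seed=0)
        with pytest.raises(ValueError):
            simdata.simulate_panel(1, 1, 10, seed=0)

    def test_every_column_polymorphic(self, small_panel):
        freqs = small_panel.allele_frequencies()
        assert np.all((freqs > 0) & (freqs < 1))

    def test_deterministic(self):
        a = simdata.simulate_panel(4, 30, 60, seed=9)
        b = simdata.simulate_panel(4, 30, 60, seed=9)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)


class TestSimulateCohort:
    def test_genotype_is_haplotype_sum(self, small_panel, small_truth):
        h = small_panel.haplotypes
        pairs = small_truth.haplotype_pairs
        expected = (h[pairs[:, 0]] + h[pairs[:, 1]]).T
        np.testing.assert_array_equal(small_truth.genotypes, expected)

    def test_identical_pair_gives_even_genotypes(self, small_panel):
        truth = simdata.simulate_cohort(small_panel, 30, seed=5)
        truth.haplotype_pairs[:] = 3
        g = small_panel.haplotypes[3] * 2
        recomputed = (
            small_panel.haplotypes[truth.haplotype_pairs[:, 0]]
            + small_panel.haplotypes[truth.haplotype_pairs[:, 1]]
        ).T
        assert np.all(recomputed % 2 == 0)
        np.testing.assert_array_equal(recomputed[:, 0], g)

    def test_cohort_frequency_converges_to_panel(self, small_panel):
        # binomial sampling oracle: freq_hat ~ Binom(2n, p) / 2n
        n = 600
        truth = simdata.simulate_cohort(small_panel, n, seed=11)
        p = small_panel.allele_frequencies()
        obs = truth.genotypes.mean(axis=1) / 2.0
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert np.mean(np.abs(obs - p) <= 3 * se) > 0.95

    def test_empty_panel_rejected(self):
        panel = simdata.simulate_panel(1, 5, 50, recomb_prob=0.0, mutation_prob=0.0, seed=0)
        with pytest.raises(ValueError):
            simdata.simulate_cohort(panel, 5, seed=0)


class TestSimulateReads:
    def test_zero_coverage_empty(self, small_truth):
        piles = simdata.simulate_reads(small_truth, mean_coverage=0.0, seed=0)
        assert len(piles.pileups) == 0

    def test_error_free_bases_match_truth(self, small_truth):
        piles = simdata.simulate_reads(
            small_truth, mean_coverage=1.0, read_error=0.0, fragment_error=0.0, seed=1
        )
        panel = small_truth.panel
        for (i, j), p in piles.pileups.items():
            alleles = {
                panel.alleles[i][panel.haplotypes[small_truth.haplotype_pairs[j, 0], i]],
                panel.alleles[i][panel.haplotypes[small_truth.haplotype_pairs[j, 1], i]],
            }
            for frag in p.fragments:
                for base, _ in frag.observations:
                    assert base in alleles

    def test_full_overlap_mates_agree_without_read_error(self, small_truth):
        piles = simdata.simulate_reads(
            small_truth, mean_coverage=1.0, read_error=0.0,
            fragment_error=0.05, overlap_fraction=1.0, seed=2,
        )
        n_pairs = 0
        for p in piles.pileups.values():
            for frag in p.fragments:
                assert len(frag.observations) == 2
                assert frag.observations[0][0] == frag.observations[1][0]
                n_pairs += 1
        assert n_pairs > 100

    def test_fragment_error_shared_by_both_mates(self, small_truth):
        # conditional on a fragment error and read_error=0, both mates show
        # the same non-allele base
        piles = simdata.simulate_reads(
            small_truth, mean_coverage=2.0, read_error=0.0,
            fragment_error=0.5, overlap_fraction=1.0, seed=3,
        )
        panel = small_truth.panel
        n_errors = 0
        for (i, j), p in piles.pileups.items():
            truth_bases = {
                panel.alleles[i][panel.haplotypes[small_truth.haplotype_pairs[j, k], i]]
                for k in (0, 1)
            }
            for frag in p.fragments:
                b0, b1 = frag.observations[0][0], frag.observations[1][0]
                assert b0 == b1
                if b0 not in truth_bases:
                    n_errors += 1
        assert n_errors > 50

    def test_depth_is_poisson(self):
        # chi-square goodness of fit on >= 1e4 site-samples
        panel = simdata.simulate_panel(6, 60, 120, seed=21)
        truth = simdata.simulate_cohort(panel, 100, seed=22)
        cov = 2.0
        piles = simdata.simulate_reads(
            truth, mean_coverage=cov, overlap_fraction=0.0, seed=23
        )
        depths = piles.depth_matrix().ravel()
        assert depths.size >= 10_000
        kmax = 9
        obs = np.bincount(np.minimum(depths, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), cov)
        probs = np.append(pmf, 1 - pmf.sum())
        chi2, p = stats.chisquare(obs, probs * depths.size)
        assert p > 0.01

    def test_overlap_keeps_expected_base_observations(self):
        panel = simdata.simulate_panel(6, 60, 80, seed=31)
        truth = simdata.simulate_cohort(panel, 80, seed=32)
        for ov in (0.0, 0.5, 1.0):
            piles = simdata.simulate_reads(
                truth, mean_coverage=2.0, overlap_fraction=ov, seed=33
            )
            mean_depth = piles.depth_matrix().mean()
            assert abs(mean_depth - 2.0) < 0.1

    def test_deterministic(self, small_truth):
        a = simdata.simulate_reads(small_truth, mean_coverage=1.0, seed=8)
        b = simdata.simulate_reads(small_truth, mean_coverage=1.0, seed=8)
        assert sorted(a.pileups) == sorted(b.pileups)
        for key in a.pileups:
            fa, fb = a.pileups[key].fragments, b.pileups[key].fragments
            assert [f.observations for f in fa] == [f.observations for f in fb]


class TestDownsample:
    def test_keep_all_is_identity(self, small_pileups):
        kept = simdata.downsample(small_pileups, 1.0, seed=0)
        assert sorted(kept.pileups) == sorted(small_pileups.pileups)
        np.testing.assert_array_equal(
            kept.depth_matrix(), small_pileups.depth_matrix()
        )

    def test_keep_none_is_empty(self, small_pileups):
        kept = simdata.downsample(small_pileups, 0.0, seed=0)
        assert len(kept.pileups) == 0

    def test_whole_fragments_kept_or_dropped(self, small_pileups):
        kept = simdata.downsample(small_pileups, 0.5, seed=4)
        for key, p in kept.pileups.items():
            original = {
                f.fragment_id: f for f in small_pileups.pileups[key].fragments
            }
            for frag in p.fragments:
                assert frag.observations == original[frag.fragment_id].observations

    def test_eighth_of_4x_is_half_x(self):
        # 12.5% of 4x reads approximates .5x coverage
        panel = simdata.simulate_panel(6, 60, 150, seed=41)
        truth = simdata.simulate_cohort(panel, 80, seed=42)
        piles = simdata.simulate_reads(
            truth, mean_coverage=4.0, overlap_fraction=0.0, seed=43
        )
        kept = simdata.downsample(piles, 0.125, seed=44)
        depths = kept.depth_matrix().ravel()
        assert depths.size >= 10_000
        se = np.sqrt(0.5 / depths.size)  # Poisson(0.5) mean has var 0.5/n
        assert abs(depths.mean() - 0.5) <= 3 * se


class TestSimulateIntensities:
    def test_zero_noise_points_at_class_means(self, small_truth):
        inten = simdata.simulate_intensities(small_truth, noise_scale=0.0, seed=5)
        for i in range(small_truth.n_snps):
            means = small_truth.true_cluster_params[i].means
            for g in range(3):
                sel = small_truth.genotypes[i] == g
                if sel.any():
                    np.testing.assert_allclose(
                        inten[i, sel], np.broadcast_to(means[g], (sel.sum(), 2))
                    )

    def test_null_probe_identical_distribution(self, small_panel):
        truth = simdata.simulate_cohort(small_panel, 400, seed=6)
        inten = simdata.simulate_intensities(
            truth, artifact_config={"null_probe": {"fraction": 0.2}}, seed=7
        )
        art = np.flatnonzero(truth.artifact_labels == "null_probe")
        assert art.size > 0
        i = art[0]
        params = truth.true_cluster_params[i]
        assert np.ptp(params.means, axis=0).max() == 0.0
        # empirical class means coincide within sampling error
        grand = inten[i].mean(axis=0)
        for g in range(3):
            sel = truth.genotypes[i] == g
            if sel.sum() > 30:
                se = inten[i, sel].std(axis=0) / np.sqrt(sel.sum())
                assert np.all(np.abs(inten[i, sel].mean(axis=0) - grand) < 4 * se + 1e-9)

    def test_class_means_match_template(self, small_panel):
        # normal-sampling oracle over >= 500 samples
        truth = simdata.simulate_cohort(small_panel, 600, seed=8)
        template = simdata.default_cluster_template()
        inten = simdata.simulate_intensities(truth, mean_jitter=0.0, seed=9)
        errs = []
        for i in range(0, truth.n_snps, 11):
            for g in range(3):
                sel = truth.genotypes[i] == g
                if sel.sum() < 30:
                    continue
                se = np.sqrt(np.diag(template.covs[g]) / sel.sum())
                errs.append(
                    np.all(np.abs(inten[i, sel].mean(axis=0) - template.means[g]) <= 3 * se)
                )
        assert np.mean(errs) > 0.9

    def test_unknown_artifact_rejected(self, small_truth):
        with pytest.raises(ValueError):
            simdata.simulate_intensities(
                small_truth, artifact_config={"bogus": {"fraction": 0.1}}, seed=0
            )


class TestErrorCovariates:
    def test_perfectly_separating_binary_flag(self, small_panel):
        truth = simdata.simulate_cohort(small_panel, 20, seed=10)
        truth.artifact_labels = np.array(
            ["null_probe" if i % 2 else "none" for i in range(truth.n_snps)],
            dtype=object,
        )
        cov = simdata.simulate_error_covariates(
            truth,
            {"flag": {"kind": "binary", "rates": {"null_probe": 1.0, "default": 0.0}}},
            seed=11,
        )
        flags = cov["flag"].to_numpy()
        assert np.all(flags[1::2] == 1) and np.all(flags[0::2] == 0)

    def test_zero_effect_is_null_calibrated(self, small_panel):
        # with no planted effect the Fisher test should be null
        truth = simdata.simulate_cohort(small_panel, 20, seed=12)
        truth.artifact_labels = np.array(
            ["null_probe" if i < truth.n_snps // 2 else "none"
             for i in range(truth.n_snps)],
            dtype=object,
        )
        pvals = []
        for seed in range(40):
            cov = simdata.simulate_error_covariates(
                truth, {"f": {"kind": "binary", "rates": {"default": 0.3}}}, seed=seed
            )
            pvals.append(
                jg.disputes.binary_enrichment(
                    cov["f"].to_numpy(), truth.artifact_labels
                )
            )
        assert np.mean(np.asarray(pvals) < 0.05) < 0.15

    def test_planted_rate_difference_has_power(self, small_panel):
        # Fisher power > 0.9 at rates 0.1 vs 0.6 with n = 200 per class
        panel = simdata.simulate_panel(6, 60, 520, recomb_prob=0.05,
                                       mutation_prob=0.01, seed=13)
        truth = simdata.simulate_cohort(panel, 10, seed=13)
        n = truth.n_snps
        assert n >= 400
        labels = np.array(
            ["null_probe" if i < 200 else "none" for i in range(n)], dtype=object
        )
        truth.artifact_labels = labels
        hits = 0
        n_trials = 100
        for seed in range(n_trials):
            cov = simdata.simulate_error_covariates(
                truth,
                {"f": {"kind": "binary",
                       "rates": {"null_probe": 0.6, "default": 0.1}}},
                seed=seed,
            )
            sel = slice(0, 400)  # 200 per class
            p = jg.disputes.binary_enrichment(
                cov["f"].to_numpy()[sel], labels[sel]
            )
            hits += p < 0.05
        assert hits / n_trials > 0.9

    def test_continuous_covariate_class_means(self, small_panel):
        truth = simdata.simulate_cohort(small_panel, 10, seed=14)
        truth.artifact_labels = np.array(
            ["cluster_shift"] * (truth.n_snps // 2)
            + ["none"] * (truth.n_snps - truth.n_snps // 2),
            dtype=object,
        )
        cov = simdata.simulate_error_covariates(
            truth,
            {"score": {"kind": "continuous",
                       "means": {"cluster_shift": 2.0, "default": 0.0},
                       "sd": 0.5}},
            seed=15,
        )
        v = cov["score"].to_numpy()
        half = truth.n_snps // 2
        assert v[:half].mean() > 1.5 and abs(v[half:].mean()) < 0.5
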
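"""Phasing / imputation over a genotype-likelihood matrix.

The joint-calling framework treats its phasing engine as a pluggable
component with a likelihood-in / posterior-out contract. The default engine
here is an iterative haploid-copying (Li-Stephens-style) HMM:

1. initialise each sample's haplotype pair by sampling genotypes from the
   per-site posterior (likelihood x genotype-frequency prior);
2. for ``n_iterations`` rounds, run a forward-backward pass for each of a
   sample's two chromosomes against the current haplotype pool (plus an
   optional reference panel), with emissions weighted by the input genotype
   likelihoods given the partner chromosome (pseudo-diploid conditioning),
   then re-sample every sample's haplotypes from the smoothed genotype
   posteriors;
3. return the genotype posteriors averaged over the iterations after a
   burn-in of the first half (the sampled haplotype pool needs a few rounds
   to become phase-coherent; early iterations are systematically noisy).

The copying prior at each site is computed with the site's own emission
excluded (leave-one-out smoothing), so the data likelihood enters the
genotype posterior exactly once. A sample's own haplotypes are masked out of
its state pool. With ``n_iterations=0`` the output is the normalised input
likelihood times an EM-free moment estimate of the genotype frequencies (the
no-LD limit).
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeLikelihoodMatrix, HaplotypePanel, PosteriorMatrix

DEFAULT_N_ITERATIONS = 20
DEFAULT_N_STATES = 100
DEFAULT_RECOMB = 0.05
DEFAULT_MISMATCH = 0.01


def moment_genotype_prior(gl: GenotypeLikelihoodMatrix) -> np.ndarray:
    """Per-site genotype frequencies: mean of the normalised likelihoods."""
    lik = gl.normalized_likelihoods()
    prior = lik.mean(axis=1)  # (S, 3)
    return prior / prior.sum(axis=1, keepdims=True)


def posterior_without_ld(gl: GenotypeLikelihoodMatrix) -> PosteriorMatrix:
    """Likelihood x moment genotype-frequency prior, normalised per entry."""
    lik = np.exp(gl.log_likelihoods - gl.log_likelihoods.max(axis=2, keepdims=True))
    post = lik * moment_genotype_prior(gl)[:, None, :]
    post /= post.sum(axis=2, keepdims=True)
    return PosteriorMatrix(post)


def sample_haplotypes(
    posteriors: PosteriorMatrix,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    allele_probs: tuple | None = None,
) -> np.ndarray:
    """Sample a haplotype pair per sample consistent with the posteriors.

    Returns a (2 * n_samples, S) binary matrix; haplotypes 2j and 2j+1
    belong to sample j. A genotype is drawn per site from its posterior
    triple. For heterozygotes, ``allele_probs`` — the per-chromosome
    alternate-allele probabilities (q1, q2), each (S, N), from the copying
    HMM — decides which chromosome carries the alternate allele
    (P(chrom 1) proportional to q1 (1 - q2)); without them the assignment is
    a fair coin. Supplying them keeps the sampled haplotypes phase-coherent
    along the chromosome, which is what lets the pool carry LD.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    post = posteriors.posteriors
    S = post.shape[0]
    if post.shape[1] != n_samples:
        raise ValueError("posterior sample dimension mismatch")
    u = rng.random((S, n_samples))
    cum = np.cumsum(post, axis=2)
    geno = (u[:, :, None] > cum).sum(axis=2)  # (S, N) in {0,1,2}
    if allele_probs is None:
        p_first = np.full((S, n_samples), 0.5)
    else:
        q1, q2 = allele_probs
        w1 = q1 * (1.0 - q2)
        w2 = (1.0 - q1) * q2
        tot = w1 + w2
        p_first = np.where(tot > 0, w1 / np.where(tot > 0, tot, 1.0), 0.5)
    first = rng.random((S, n_samples)) < p_first
    haps = np.zeros((2 * n_samples, S), dtype=np.int8)
    a1 = np.where(geno == 2, 1, np.where((geno == 1) & first, 1, 0))
    a2 = np.where(geno == 2, 1, np.where((geno == 1) & ~first, 1, 0))
    haps[0::2] = a1.T
    haps[1::2] = a2.T
    return haps


def _forward_backward_alleles(
    pool: np.ndarray,
    emit: np.ndarray,
    self_mask: np.ndarray,
    recomb: float,
    mismatch: float,
) -> np.ndarray:
    """Leave-one-out allele prior from a haploid copying HMM, all samples at once.

    pool: (K, S) template haplotypes. emit: (S, N, K) per-site emission
    weights (likelihood of the data given the copied allele and the partner
    chromosome). self_mask: (N, K), zero where state k is the sample's own
    haplotype. Returns prior allele-1 probabilities (S, N) computed from
    state posteriors that exclude the site's own emission.
    """
    S = pool.shape[1]
    N, K = self_mask.shape
    init = self_mask / self_mask.sum(axis=1, keepdims=True)

    # forward, storing the one-step predictive distribution at each site
    pred = np.empty((S, N, K))
    alpha = init.copy()
    for s in range(S):
        pred[s] = alpha
        alpha = alpha * emit[s]
        tot = alpha.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        alpha /= tot
        # transition: stay w.p. 1-r, else jump uniformly over allowed states
        alpha = (1.0 - recomb) * alpha + recomb * init

    # backward
    gamma_excl = np.empty((S, N, K))
    beta = np.ones((N, K))
    for s in range(S - 1, -1, -1):
        gamma_excl[s] = pred[s] * beta * self_mask
        tot = gamma_excl[s].sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        gamma_excl[s] /= tot
        b = beta * emit[s]
        beta = (1.0 - recomb) * b + recomb * (b * init).sum(axis=1, keepdims=True)
        tot = beta.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        beta /= tot

    # allele prior: copied allele flips with prob = mismatch
    p_alt = np.einsum("snk,ks->sn", gamma_excl, pool.astype(float))
    return p_alt * (1.0 - mismatch) + (1.0 - p_alt) * mismatch


def phase_impute(
    gl: GenotypeLikelihoodMatrix,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    n_states: int = DEFAULT_N_STATES,
    recomb_param: float = DEFAULT_RECOMB,
    mismatch_param: float = DEFAULT_MISMATCH,
    reference_panel: HaplotypePanel | None = None,
    seed: int = 0,
) -> PosteriorMatrix:
    """LD-aware genotype posteriors from a genotype-likelihood matrix.

    See the module docstring for the algorithm. The result is deterministic
    given ``seed``; with ``n_iterations=0`` it reduces to
    :func:`posterior_without_ld`.
    """
    if gl.n_snps == 0 or gl.n_samples == 0:
        raise ValueError("genotype-likelihood matrix must be non-empty")
    if n_iterations == 0:
        return posterior_without_ld(gl)

    S, N = gl.n_snps, gl.n_samples
    n_panel = reference_panel.n_haplotypes if reference_panel is not None else 0
    if 2 * N + n_panel < 2:
        raise ValueError("need at least 2 haplotype sources")

    rng = np.random.default_rng(seed)
    lik = np.exp(gl.log_likelihoods - gl.log_likelihoods.max(axis=2, keepdims=True))
    lik /= lik.sum(axis=2, keepdims=True)  # (S, N, 3)

    haps = sample_haplotypes(posterior_without_ld(gl), N, rng)  # (2N, S)
    if reference_panel is not None:
        if reference_panel.n_snps != S:
            raise ValueError("reference panel SNP dimension mismatch")
        panel_haps = reference_panel.haplotypes

    # choose the state pool once: indices into the stacked (samples + panel)
    # haplotype set, capped at n_states
    total = 2 * N + n_panel
    k = min(n_states, total)
    pool_idx = rng.choice(total, size=k, replace=False) if k < total else np.arange(total)
    pool_owner = np.where(pool_idx < 2 * N, pool_idx // 2, -1)  # sample of origin
    self_mask = np.ones((N, k))
    for col, owner in enumerate(pool_owner):
        if owner >= 0:
            self_mask[owner, col] = 0.0
    bad = self_mask.sum(axis=1) == 0
    if bad.any():  # degenerate pools: allow self-copying rather than fail
        self_mask[bad] = 1.0

    accum = np.zeros((S, N, 3))
    burn_in = n_iterations // 2
    n_kept = 0
    for it in range(n_iterations):
        stacked = (
            np.vstack([haps, panel_haps]) if reference_panel is not None else haps
        )
        pool = stacked[pool_idx]  # (k, S)
        pool_alt = pool.T.astype(float)  # (S, k)

        post = np.empty((S, N, 3))
        partner = [haps[1::2], haps[0::2]]  # (N, S) partner of hap 0 / hap 1
        allele_priors = []
        for which in range(2):
            h_other = partner[which].T  # (S, N)
            # emission for state k at site s, sample n:
            #   sum_a P(copied allele -> a) * lik[s, n, a + h_other]
            l_g = np.take_along_axis(
                lik, (h_other[:, :, None] + np.array([0, 1])[None, None, :]), axis=2
            )  # (S, N, 2): likelihood if this chromosome carries allele 0 / 1
            e_allele0 = (1.0 - mismatch_param) * l_g[:, :, 0] + mismatch_param * l_g[
                :, :, 1
            ]
            e_allele1 = (1.0 - mismatch_param) * l_g[:, :, 1] + mismatch_param * l_g[
                :, :, 0
            ]
            emit = (
                e_allele0[:, :, None] * (1.0 - pool_alt)[:, None, :]
                + e_allele1[:, :, None] * pool_alt[:, None, :]
            )  # (S, N, K)
            p_alt = _forward_backward_alleles(
                pool, emit, self_mask, recomb_param, mismatch_param
            )
            allele_priors.append(p_alt)

        q1, q2 = allele_priors
        prior_g = np.stack(
            [
                (1 - q1) * (1 - q2),
                q1 * (1 - q2) + (1 - q1) * q2,
                q1 * q2,
            ],
            axis=2,
        )
        post = lik * prior_g
        post /= post.sum(axis=2, keepdims=True)
        if it >= burn_in:
            accum += post
            n_kept += 1
        haps = sample_haplotypes(
            PosteriorMatrix(post), N, rng, allele_probs=(q1, q2)
        )

    accum /= n_kept
    accum /= accum.sum(axis=2, keepdims=True)
    out = PosteriorMatrix(accum)
    out.validate()
    return out
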
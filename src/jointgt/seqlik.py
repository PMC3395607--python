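"""Diploid genotype likelihoods from pileups.

Two likelihood models are provided:

* **read mode** — the conventional model in which every base observation is
  treated independently: P(b | g) = (P(b | A) + P(b | B)) / 2 for genotype
  g = {A, B}, with the standard Phred model P(b | h) = 1 - e on match and
  e/3 on mismatch, e = 10^(-q/10).

* **fragment mode** — overlapping mates of a read pair derive from one DNA
  fragment, so an error introduced during shearing / library preparation
  (rate p, around 1e-4) appears in *both* mates but should be penalised only
  once. The fragment likelihood marginalises over the (unobserved) fragment
  template base f:

      P(frag | g={A,B}) = 1/2 * sum_{h in {A,B}} sum_{f in ACGT}
                            P(f | h; p) * prod_k P(b_k | q_k, f)

  with P(f | h; p) = 1 - p if f = h else p/3.

For single-covering mates at p = 0 the two models coincide for homozygous
genotypes. Likelihood triples are max-normalised (PL-style) and held in log
space to avoid underflow.
"""

from __future__ import annotations

import numpy as np

from .containers import BASES, BASE_INDEX, FragmentObservation, PileupSet, SitePileup

DEFAULT_FRAGMENT_ERROR = 1e-4
_LOG_TINY = -745.0  # below exp() underflow


def phred_to_error(qual: float) -> float:
    return 10.0 ** (-qual / 10.0)


def base_obs_likelihood(observed: str, qual: float, hypothesized: str) -> float:
    """P(observed base | true base), standard symmetric Phred model."""
    if observed not in BASE_INDEX or hypothesized not in BASE_INDEX:
        raise ValueError(f"invalid base symbol {observed!r} / {hypothesized!r}")
    if qual < 0:
        raise ValueError("Phred quality must be >= 0")
    e = phred_to_error(qual)
    return 1.0 - e if observed == hypothesized else e / 3.0


def fragment_genotype_likelihood(
    frag: FragmentObservation,
    alleles: tuple,
    fragment_error: float = DEFAULT_FRAGMENT_ERROR,
) -> float:
    """Fragment likelihood under genotype {A_allele, B_allele}.

    Marginalises over the originating haplotype h (uniform over the two
    genotype alleles) and the fragment template base f, so a shared error in
    an overlapping pair costs one factor of p rather than two factors of e.
    """
    if not 0.0 <= fragment_error <= 1.0:
        raise ValueError("fragment_error must lie in [0, 1]")
    a_allele, b_allele = alleles
    total = 0.0
    for h in (a_allele, b_allele):
        for f in BASES:
            p_f = 1.0 - fragment_error if f == h else fragment_error / 3.0
            prod = p_f
            for base, qual in frag.observations:
                prod *= base_obs_likelihood(base, qual, f)
            total += prod
    return 0.5 * total


def read_independent_genotype_likelihood(pileup: SitePileup, alleles: tuple) -> float:
    """Conventional read-based likelihood: every observation independent."""
    a_allele, b_allele = alleles
    prod = 1.0
    for frag in pileup.fragments:
        for base, qual in frag.observations:
            prod *= 0.5 * (
                base_obs_likelihood(base, qual, a_allele)
                + base_obs_likelihood(base, qual, b_allele)
            )
    return prod


def site_genotype_likelihoods(
    pileup: SitePileup,
    fragment_error: float = DEFAULT_FRAGMENT_ERROR,
    mode: str = "fragment",
) -> np.ndarray:
    """Normalised likelihood triple over (ref/ref, ref/alt, alt/alt).

    ``mode`` selects the fragment-aware or read-independent model. Bases
    that match neither allele still contribute as mismatch evidence against
    both. The triple is scaled so its maximum is 1; an empty pileup yields
    (1, 1, 1).
    """
    if mode not in ("fragment", "read"):
        raise ValueError(f"mode must be 'fragment' or 'read', got {mode!r}")
    r, a = pileup.ref_base, pileup.alt_base
    genotypes = ((r, r), (r, a), (a, a))
    if not pileup.fragments:
        return np.ones(3)
    log_lik = np.zeros(3)
    for g, alleles in enumerate(genotypes):
        if mode == "fragment":
            for frag in pileup.fragments:
                log_lik[g] += _safe_log(
                    fragment_genotype_likelihood(frag, alleles, fragment_error)
                )
        else:
            log_lik[g] = _safe_log(
                read_independent_genotype_likelihood(pileup, alleles)
            )
    log_lik -= log_lik.max()
    return np.exp(log_lik)


def _safe_log(x: float) -> float:
    return np.log(x) if x > 0 else _LOG_TINY


# ---------------------------------------------------------------------------
# Vectorised batch path used by the joint-calling pipeline. Must agree with
# the scalar functions above (unit-tested).
# ---------------------------------------------------------------------------


def pileup_log_likelihood_matrix(
    pileups: PileupSet,
    fragment_error: float = DEFAULT_FRAGMENT_ERROR,
    mode: str = "fragment",
) -> np.ndarray:
    """(S, N, 3) max-normalised genotype log-likelihoods for a whole cohort.

    Entries with no coverage are flat (all zero). Equivalent to calling
    :func:`site_genotype_likelihoods` per pileup, but vectorised.
    """
    if mode not in ("fragment", "read"):
        raise ValueError(f"mode must be 'fragment' or 'read', got {mode!r}")
    S, N = len(pileups.snp_ids), len(pileups.sample_ids)
    out = np.zeros((S, N, 3))
    if not pileups.pileups:
        return out

    # flatten all observations: fragment-major order
    keys = sorted(pileups.pileups)
    frag_site = []  # per fragment: pileup index into keys
    obs_base = []
    obs_qual = []
    obs_frag = []  # per observation: fragment index
    frag_count = []
    for ki, key in enumerate(keys):
        p = pileups.pileups[key]
        for frag in p.fragments:
            fi = len(frag_site)
            frag_site.append(ki)
            frag_count.append(len(frag.observations))
            for base, qual in frag.observations:
                obs_base.append(BASE_INDEX[base])
                obs_qual.append(qual)
                obs_frag.append(fi)
    obs_base = np.asarray(obs_base)
    obs_qual = np.asarray(obs_qual, dtype=float)
    obs_frag = np.asarray(obs_frag)
    frag_site_arr = np.asarray(frag_site)
    n_frag = len(frag_site)

    # per-observation likelihood vs each of the 4 template bases: (n_obs, 4)
    e = 10.0 ** (-obs_qual / 10.0)
    obs_lik = np.tile((e / 3.0)[:, None], (1, 4))
    obs_lik[np.arange(len(obs_base)), obs_base] = 1.0 - e

    # per-fragment product over its observations: (n_frag, 4)
    frag_prod = np.ones((n_frag, 4))
    np.multiply.at(frag_prod, obs_frag, obs_lik)

    # marginalise the fragment template base for each possible haplotype h
    p = fragment_error
    if mode == "fragment":
        # hap_lik[f, h] = sum_f' P(f'|h) * frag_prod[f, f']
        mix = np.full((4, 4), p / 3.0)
        np.fill_diagonal(mix, 1.0 - p)
        hap_lik = frag_prod @ mix  # (n_frag, 4)
    else:
        hap_lik = frag_prod  # template base == haplotype base, no mixing

    ref_idx = np.array([BASE_INDEX[r] for r, _ in pileups.alleles])
    alt_idx = np.array([BASE_INDEX[a] for _, a in pileups.alleles])
    key_site = np.array([k[0] for k in keys])
    frag_ref = ref_idx[key_site[frag_site_arr]]
    frag_alt = alt_idx[key_site[frag_site_arr]]

    idx = np.arange(n_frag)
    l_ref = hap_lik[idx, frag_ref]
    l_alt = hap_lik[idx, frag_alt]
    if mode == "fragment":
        gl = np.stack([l_ref, 0.5 * (l_ref + l_alt), l_alt], axis=1)
        log_gl = np.where(gl > 0, np.log(np.maximum(gl, 1e-320)), _LOG_TINY)
    else:
        # read mode: product over observations of the per-read diploid average
        obs_ref = obs_lik[np.arange(len(obs_base)), frag_ref[obs_frag]]
        obs_alt = obs_lik[np.arange(len(obs_base)), frag_alt[obs_frag]]
        per_obs = np.stack(
            [obs_ref, 0.5 * (obs_ref + obs_alt), obs_alt], axis=1
        )
        log_per_obs = np.where(
            per_obs > 0, np.log(np.maximum(per_obs, 1e-320)), _LOG_TINY
        )
        log_gl = np.zeros((n_frag, 3))
        np.add.at(log_gl, obs_frag, log_per_obs)

    # sum fragment log-likelihoods within each pileup
    site_log = np.zeros((len(keys), 3))
    np.add.at(site_log, frag_site_arr, log_gl)
    site_log -= site_log.max(axis=1, keepdims=True)
    for ki, (i, j) in enumerate(keys):
        out[i, j] = site_log[ki]
    return out
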
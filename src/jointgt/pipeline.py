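"""The outer joint-calling framework.

Genotype posteriors are estimated jointly from SNP-array intensities and
sequence genotype likelihoods under a naive-Bayes model: intensity and
sequence data are conditionally independent given the true genotype. An EM
loop alternates between

* E-step: per-SNP intensity likelihoods (current cluster parameters) are
  multiplied with the fixed sequence likelihoods; LD-aware posteriors are
  then obtained by phasing / imputation across SNPs and samples;
* M-step: per-SNP cluster parameters are re-estimated from the intensity
  points weighted by the posterior responsibilities.

The loop runs a fixed number of outer iterations (default 3, no convergence
test). Single-technology and no-imputation ablations are switched by config
flags; samples or entries without one data type simply contribute flat
likelihoods from that source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import intensity as _intensity
from . import ldimpute, seqlik
from .containers import (
    CallSet,
    ClusterParams,
    GenotypeLikelihoodMatrix,
    NO_CALL,
    PileupSet,
    PosteriorMatrix,
)

logger = logging.getLogger(__name__)

DEFAULT_GQ_CAP = 99.0


@dataclass
class JointCallConfig:
    """Configuration for a joint-calling run (all ablation switches)."""

    outer_iterations: int = 3
    gq_threshold: float = 10.0
    use_array: bool = True
    use_sequence: bool = True
    use_imputation: bool = True
    recluster: bool = True
    seq_mode: str = "fragment"  # or "read"
    fragment_error: float = seqlik.DEFAULT_FRAGMENT_ERROR
    ld_iterations: int = ldimpute.DEFAULT_N_ITERATIONS
    ld_states: int = ldimpute.DEFAULT_N_STATES
    ld_recomb: float = ldimpute.DEFAULT_RECOMB
    ld_mismatch: float = ldimpute.DEFAULT_MISMATCH
    gq_cap: float = DEFAULT_GQ_CAP
    seed: int = 0
    cluster_template: ClusterParams | None = None

    def __post_init__(self) -> None:
        if not (self.use_array or self.use_sequence):
            raise ValueError("at least one of use_array / use_sequence required")
        if self.gq_threshold < 0:
            raise ValueError("gq_threshold must be >= 0")


@dataclass
class JointCallResult:
    calls: CallSet
    posteriors: PosteriorMatrix
    cluster_params: list  # per-SNP ClusterParams (empty if use_array=False)
    log_likelihood_trace: list = field(default_factory=list)


def combine_likelihoods(seq_gl, array_gl) -> np.ndarray:
    """Naive-Bayes combination: elementwise product, max-normalised.

    Either source may be None / missing (treated as flat); both missing
    yields a flat, uninformative triple.
    """
    if seq_gl is None and array_gl is None:
        return np.ones(3)
    out = np.ones(3)
    for gl in (seq_gl, array_gl):
        if gl is not None:
            out = out * np.asarray(gl, dtype=float)
    m = out.max()
    if m <= 0:
        return np.ones(3)
    return out / m


def posterior_to_calls(
    posteriors: PosteriorMatrix,
    gq_threshold: float = 10.0,
    gq_cap: float = DEFAULT_GQ_CAP,
) -> CallSet:
    """Threshold posteriors into calls.

    The most likely genotype is called iff its posterior exceeds
    1 - 10^(-gq_threshold / 10) (GQ 10 <-> 90%, GQ 20 <-> 99%); exact ties
    between the top two posteriors give a no-call. GQ = -10 log10(1 - top),
    capped.
    """
    post = posteriors.posteriors
    order = np.argsort(post, axis=2)
    top_idx = order[:, :, 2]
    top = np.take_along_axis(post, top_idx[:, :, None], axis=2)[:, :, 0]
    second = np.take_along_axis(post, order[:, :, 1][:, :, None], axis=2)[:, :, 0]
    threshold = 1.0 - 10.0 ** (-gq_threshold / 10.0)

    # ties broken toward the lower genotype index for GQ, no-call for calls
    tie = top == second
    lower = np.minimum(top_idx, np.where(tie, order[:, :, 1], top_idx))
    genotype = np.where((top > threshold) & ~tie, top_idx, NO_CALL).astype(np.int8)
    with np.errstate(divide="ignore"):
        gq = -10.0 * np.log10(np.maximum(1.0 - top, 10.0 ** (-gq_cap / 10.0)))
    gq = np.minimum(gq, gq_cap)
    gq = np.where(genotype == NO_CALL, 0.0, gq)
    _ = lower  # tie diagnostics only
    return CallSet(genotypes=genotype, gq=gq, posteriors=post)


def sequence_log_likelihoods(
    pileups: PileupSet, config: JointCallConfig, positions=None
) -> GenotypeLikelihoodMatrix:
    """Per-site sequence genotype log-likelihoods for the whole cohort."""
    ll = seqlik.pileup_log_likelihood_matrix(
        pileups, fragment_error=config.fragment_error, mode=config.seq_mode
    )
    S = len(pileups.snp_ids)
    if positions is None:
        positions = np.arange(1, S + 1) * 1000
    missing = np.ones((S, len(pileups.sample_ids)), dtype=bool)
    for key in pileups.pileups:
        missing[key] = False
    return GenotypeLikelihoodMatrix(
        log_likelihoods=ll,
        positions=positions,
        alleles=list(pileups.alleles),
        snp_ids=list(pileups.snp_ids),
        sample_ids=list(pileups.sample_ids),
        missing=missing,
    )


def _check_universes(gl: GenotypeLikelihoodMatrix, intensities: np.ndarray) -> None:
    S, N = gl.n_snps, gl.n_samples
    if intensities.shape[:2] != (S, N):
        raise ValueError(
            "inconsistent SNP/sample universes: sequence likelihoods are "
            f"{S} SNPs x {N} samples but intensities are "
            f"{intensities.shape[0]} x {intensities.shape[1]}"
        )


def joint_call(
    intensities: np.ndarray | None,
    seq_gl: GenotypeLikelihoodMatrix | None = None,
    pileups: PileupSet | None = None,
    config: JointCallConfig | None = None,
) -> JointCallResult:
    """Run the full joint-calling EM and emit thresholded genotype calls.

    ``intensities`` is an (S, N, 2) array (NaN = missing); sequence evidence
    is either a ready-made GL matrix or raw pileups. Cluster parameters are
    initialised once, then ``outer_iterations`` E/M rounds are run; the final
    posteriors are thresholded at ``gq_threshold``.
    """
    config = config or JointCallConfig()
    if seq_gl is None:
        if pileups is None:
            raise ValueError("a GL matrix or pileups is required to define the site set")
        seq_gl = sequence_log_likelihoods(pileups, config)
    if config.use_array:
        if intensities is None:
            raise ValueError("use_array=True requires intensities")
        intensities = np.asarray(intensities, dtype=float)
        _check_universes(seq_gl, intensities)

    S, N = seq_gl.n_snps, seq_gl.n_samples
    seq_ll = seq_gl.log_likelihoods if config.use_sequence else np.zeros((S, N, 3))

    template = config.cluster_template
    if template is None:
        from .simdata import default_cluster_template

        template = default_cluster_template()

    clusters: list = []
    array_ll = np.zeros((S, N, 3))
    if config.use_array:
        for i in range(S):
            params, _ = _intensity.init_clusters(intensities[i], template)
            clusters.append(params)
            array_ll[i] = _intensity.log_likelihood_matrix(intensities[i], params)

    trace: list = []
    posteriors = None
    n_rounds = max(1, config.outer_iterations)
    for it in range(n_rounds):
        joint_ll = seq_ll + array_ll
        gl = GenotypeLikelihoodMatrix(
            log_likelihoods=joint_ll - joint_ll.max(axis=2, keepdims=True),
            positions=seq_gl.positions,
            alleles=seq_gl.alleles,
            snp_ids=seq_gl.snp_ids,
            sample_ids=seq_gl.sample_ids,
        )
        if config.use_imputation:
            posteriors = ldimpute.phase_impute(
                gl,
                n_iterations=config.ld_iterations,
                n_states=config.ld_states,
                recomb_param=config.ld_recomb,
                mismatch_param=config.ld_mismatch,
                seed=config.seed + it,
            )
        else:
            lik = np.exp(gl.log_likelihoods)
            posteriors = PosteriorMatrix(lik / lik.sum(axis=2, keepdims=True))

        # expected complete-data log-likelihood under the current posteriors
        # (per-entry max-normalised; the trend across iterations is the
        # diagnostic, not the absolute value)
        norm_ll = joint_ll - joint_ll.max(axis=2, keepdims=True)
        data_ll = float((posteriors.posteriors * norm_ll).sum())
        trace.append(data_ll)
        logger.info(
            "outer iteration %d: expected data log-likelihood %.2f", it, data_ll
        )

        if config.outer_iterations == 0:
            break  # clusters stay at initialisation; posteriors from init E-step
        if config.use_array and config.recluster:
            for i in range(S):
                clusters[i] = _intensity.mstep_update(
                    intensities[i], posteriors.posteriors[i], template
                )
                array_ll[i] = _intensity.log_likelihood_matrix(
                    intensities[i], clusters[i]
                )

    calls = posterior_to_calls(posteriors, config.gq_threshold, config.gq_cap)
    return JointCallResult(
        calls=calls,
        posteriors=posteriors,
        cluster_params=clusters,
        log_likelihood_trace=trace,
    )
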
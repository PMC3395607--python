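"""Core in-memory containers shared across the package.

Conventions
-----------
* Genotypes are non-reference allele counts in {0, 1, 2}; -1 marks a no-call.
* Matrices are laid out SNPs x samples (x 3 genotype classes where relevant).
* Genotype likelihoods are stored in natural-log space, max-normalised per
  (SNP, sample) so the largest entry is 0.
* Internal coordinates are 0-based; VCF emission converts to 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Sentinel genotype value for a no-call.
NO_CALL = -1


@dataclass
class ClusterParams:
    """Three-class bivariate-Gaussian intensity mixture for one SNP.

    Class index equals the non-reference allele count; means are ordered so
    the allele contrast (a - b) is monotone decreasing in the class index.
    """

    means: np.ndarray  # (3, 2)
    covs: np.ndarray  # (3, 2, 2)
    priors: np.ndarray  # (3,)
    uninformed: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).reshape(3, 2)
        self.covs = np.asarray(self.covs, dtype=float).reshape(3, 2, 2)
        self.priors = np.asarray(self.priors, dtype=float).reshape(3)

    def validate(self, eps: float = 0.0) -> None:
        if not np.all(self.priors >= 0) or abs(self.priors.sum() - 1.0) > 1e-6:
            raise ValueError("cluster priors must be non-negative and sum to 1")
        for g in range(3):
            w = np.linalg.eigvalsh(self.covs[g])
            if w.min() < eps - 1e-12:
                raise ValueError(f"covariance for class {g} below eigenvalue floor")

    def copy(self) -> "ClusterParams":
        return ClusterParams(
            self.means.copy(), self.covs.copy(), self.priors.copy(), self.uninformed
        )


@dataclass
class FragmentObservation:
    """Base observations from one sequenced DNA fragment at one site.

    One entry per covering mate: a single read, or two overlapping mates that
    share the fragment's template base (and hence any library-prep error).
    """

    fragment_id: str
    observations: list  # list of (base, phred_qual), length 1 or 2

    def __post_init__(self) -> None:
        if not 1 <= len(self.observations) <= 2:
            raise ValueError("a fragment covers a site with 1 or 2 mates")
        for base, qual in self.observations:
            if base not in BASE_INDEX:
                raise ValueError(f"invalid base symbol {base!r}")
            if qual < 0:
                raise ValueError("Phred quality must be >= 0")


@dataclass
class SitePileup:
    """All fragments covering one SNP in one sample."""

    snp_id: str
    sample_id: str
    ref_base: str
    alt_base: str
    fragments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt alleles must differ")
        ids = [f.fragment_id for f in self.fragments]
        if len(ids) != len(set(ids)):
            raise ValueError("fragment ids must be unique within a pileup")

    @property
    def depth(self) -> int:
        return sum(len(f.observations) for f in self.fragments)


@dataclass
class PileupSet:
    """Sparse collection of pileups for a SNP x sample grid.

    Only non-empty pileups are stored; an absent key means zero coverage.
    """

    snp_ids: list
    sample_ids: list
    alleles: list  # per-SNP (ref, alt)
    pileups: dict = field(default_factory=dict)  # (snp_idx, sample_idx) -> SitePileup

    def get(self, snp_idx: int, sample_idx: int) -> SitePileup | None:
        return self.pileups.get((snp_idx, sample_idx))

    def depth_matrix(self) -> np.ndarray:
        d = np.zeros((len(self.snp_ids), len(self.sample_ids)), dtype=int)
        for (i, j), p in self.pileups.items():
            d[i, j] = p.depth
        return d


@dataclass
class GenotypeLikelihoodMatrix:
    """SNPs x samples x 3 genotype log-likelihoods with site metadata."""

    log_likelihoods: np.ndarray  # (S, N, 3), max-normalised to 0 per entry
    positions: np.ndarray  # (S,)
    alleles: list  # per-SNP (ref, alt)
    snp_ids: list
    sample_ids: list
    missing: np.ndarray | None = None  # (S, N) bool; True = no data

    def __post_init__(self) -> None:
        self.log_likelihoods = np.asarray(self.log_likelihoods, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.log_likelihoods.ndim != 3 or self.log_likelihoods.shape[2] != 3:
            raise ValueError("log-likelihoods must be SNPs x samples x 3")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.missing is None:
            self.missing = np.zeros(self.log_likelihoods.shape[:2], dtype=bool)

    @property
    def n_snps(self) -> int:
        return self.log_likelihoods.shape[0]

    @property
    def n_samples(self) -> int:
        return self.log_likelihoods.shape[1]

    def normalized_likelihoods(self) -> np.ndarray:
        """Per-entry likelihood triples rescaled to sum to 1."""
        ll = self.log_likelihoods - self.log_likelihoods.max(axis=2, keepdims=True)
        lik = np.exp(ll)
        return lik / lik.sum(axis=2, keepdims=True)


@dataclass
class PosteriorMatrix:
    """SNPs x samples x 3 genotype posterior probabilities."""

    posteriors: np.ndarray

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.posteriors.ndim != 3 or self.posteriors.shape[2] != 3:
            raise ValueError("posteriors must be SNPs x samples x 3")

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.posteriors < -atol):
            raise ValueError("negative posterior probability")
        sums = self.posteriors.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("posterior triples must sum to 1")


@dataclass
class CallSet:
    """Thresholded genotype calls with Phred-scaled qualities.

    ``genotypes`` holds {0,1,2} or NO_CALL (-1); ``gq`` is -10*log10(1 - top
    posterior), capped; no-call entries have gq 0.
    """

    genotypes: np.ndarray  # (S, N) int8
    gq: np.ndarray  # (S, N) float
    posteriors: np.ndarray | None = None  # (S, N, 3) source posteriors

    @property
    def called(self) -> np.ndarray:
        return self.genotypes != NO_CALL

    def n_called(self) -> int:
        return int(self.called.sum())


@dataclass
class HaplotypePanel:
    """Binary haplotype matrix (haplotypes x SNPs) with LD structure."""

    haplotypes: np.ndarray  # (H, S) of {0, 1}
    positions: np.ndarray  # (S,) strictly increasing bp coordinates
    alleles: list  # per-SNP (ref_base, alt_base)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.n_snps and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        for ref, alt in self.alleles:
            if ref == alt or ref not in BASE_INDEX or alt not in BASE_INDEX:
                raise ValueError(f"invalid allele pair ({ref}, {alt})")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cohort.

    genotypes[s, n] = sum of the sample's two haplotype alleles at SNP s.
    artifact_labels mark planted array failure modes; covariates carry the
    per-SNP error-mode table together with the spec that generated it.
    """

    panel: HaplotypePanel
    genotypes: np.ndarray  # (S, N) of {0,1,2}
    haplotype_pairs: np.ndarray  # (N, 2) indices into panel
    sample_ids: list
    snp_ids: list
    artifact_labels: np.ndarray | None = None  # (S,) str
    covariates: object | None = None  # pandas.DataFrame, SNPs as rows
    covariate_spec: dict | None = None
    true_cluster_params: list | None = None  # per-SNP ClusterParams

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]
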
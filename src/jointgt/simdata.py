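"""Synthetic cohorts with the statistical structure joint calling assumes.

The generator produces, from one seeded RNG per operation:

* an LD-structured haplotype panel (founder haplotypes plus recombinant
  mosaic copies with mutation),
* diploid cohorts drawn from the panel,
* low-coverage pileups in which library-preparation (PCR) errors are shared
  by both mates of an overlapping read pair while sequencing errors are
  independent per read,
* three-cluster bivariate array intensities with planted artifact modes, and
* per-SNP error-mode covariates with configurable class enrichment.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    BASES,
    ClusterParams,
    FragmentObservation,
    HaplotypePanel,
    PileupSet,
    SitePileup,
    SyntheticTruth,
)

ARTIFACT_CLASSES = ("none", "cluster_shift", "merged_clusters", "null_probe")


def _draw_alleles(rng: np.random.Generator, n_snps: int) -> list:
    """Random (ref, alt) pairs; ref != alt."""
    refs = rng.integers(0, 4, size=n_snps)
    alts = (refs + rng.integers(1, 4, size=n_snps)) % 4
    return [(BASES[r], BASES[a]) for r, a in zip(refs, alts)]


def simulate_panel(
    n_founders: int,
    n_haplotypes: int,
    n_snps: int,
    recomb_prob: float = 0.05,
    mutation_prob: float = 0.002,
    seed: int = 0,
    position_spacing: int = 1000,
) -> HaplotypePanel:
    """Build a haplotype panel by mosaic copying of founder haplotypes.

    Founders carry independent Bernoulli(1/2) alleles; each additional
    haplotype copies a founder, switching to a random founder with
    probability ``recomb_prob`` at each adjacent-SNP step, then mutates each
    site independently with probability ``mutation_prob``. Columns left
    monomorphic are dropped, so the returned panel may have fewer SNPs than
    requested (possibly zero in degenerate settings).
    """
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if n_haplotypes < 2:
        raise ValueError("a panel needs at least 2 haplotypes")
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    for name, p in (("recomb_prob", recomb_prob), ("mutation_prob", mutation_prob)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    founders = rng.integers(0, 2, size=(n_founders, n_snps)).astype(np.int8)

    haps = np.empty((n_haplotypes, n_snps), dtype=np.int8)
    n_copy = min(n_founders, n_haplotypes)
    haps[:n_copy] = founders[:n_copy]
    for h in range(n_copy, n_haplotypes):
        source = rng.integers(0, n_founders)
        switches = rng.random(n_snps) < recomb_prob
        hap = np.empty(n_snps, dtype=np.int8)
        for s in range(n_snps):
            if s > 0 and switches[s]:
                source = rng.integers(0, n_founders)
            hap[s] = founders[source, s]
        haps[h] = hap
    mutations = rng.random((n_haplotypes, n_snps)) < mutation_prob
    haps = np.where(mutations, 1 - haps, haps).astype(np.int8)

    freqs = haps.mean(axis=0)
    keep = (freqs > 0) & (freqs < 1)
    positions = (np.arange(n_snps, dtype=np.int64) + 1) * position_spacing
    alleles = _draw_alleles(rng, n_snps)
    return HaplotypePanel(
        haplotypes=haps[:, keep],
        positions=positions[keep],
        alleles=[a for a, k in zip(alleles, keep) if k],
    )


def simulate_cohort(
    panel: HaplotypePanel, n_samples: int, seed: int = 0
) -> SyntheticTruth:
    """Draw diploid samples as random haplotype pairs (with replacement)."""
    if panel.n_snps == 0 or panel.n_haplotypes == 0:
        raise ValueError("panel must be non-empty")
    rng = np.random.default_rng(seed)
    pairs = rng.integers(0, panel.n_haplotypes, size=(n_samples, 2))
    genotypes = (
        panel.haplotypes[pairs[:, 0]] + panel.haplotypes[pairs[:, 1]]
    ).T.astype(np.int8)
    return SyntheticTruth(
        panel=panel,
        genotypes=genotypes,
        haplotype_pairs=pairs,
        sample_ids=[f"sample{j:04d}" for j in range(n_samples)],
        snp_ids=[f"snp{i:05d}" for i in range(panel.n_snps)],
    )


def _phred_from_error(read_error: float, cap: int = 60) -> int:
    if read_error <= 0:
        return cap
    return int(min(cap, round(-10.0 * np.log10(read_error))))


def simulate_reads(
    truth: SyntheticTruth,
    mean_coverage: float = 1.0,
    read_error: float = 0.001,
    fragment_error: float = 1e-4,
    overlap_fraction: float = 0.2,
    seed: int = 0,
) -> PileupSet:
    """Simulate low-coverage pileups with fragment-shared errors.

    Per site and sample the fragment count is Poisson with rate
    ``mean_coverage / (1 + overlap_fraction)`` so the expected number of base
    observations is ``mean_coverage``. Each fragment carries one of the
    sample's two true alleles; with probability ``fragment_error`` the
    fragment's template base mutates (uniformly to one of the 3 other bases)
    before sequencing, so both mates of an overlapping pair see the same
    wrong base. Each mate is then re-mutated independently with probability
    ``read_error``. ``read_error`` may be given as a probability or a Phred
    score (values > 1 are treated as Phred).
    """
    if mean_coverage < 0:
        raise ValueError("mean_coverage must be >= 0")
    if read_error > 1.0:  # Phred input
        read_error = 10.0 ** (-read_error / 10.0)
    for name, p in (
        ("read_error", read_error),
        ("fragment_error", fragment_error),
        ("overlap_fraction", overlap_fraction),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    qual = _phred_from_error(read_error)
    panel = truth.panel
    lam = mean_coverage / (1.0 + overlap_fraction)

    pileups: dict = {}
    n_frags = rng.poisson(lam, size=(truth.n_snps, truth.n_samples))
    for i in range(truth.n_snps):
        ref, alt = panel.alleles[i]
        allele_bases = (ref, alt)
        hap_a = panel.haplotypes[truth.haplotype_pairs[:, 0], i]
        hap_b = panel.haplotypes[truth.haplotype_pairs[:, 1], i]
        for j in range(truth.n_samples):
            k = n_frags[i, j]
            if k == 0:
                continue
            frags = []
            for f in range(k):
                allele = hap_a[j] if rng.random() < 0.5 else hap_b[j]
                base = allele_bases[allele]
                if fragment_error > 0 and rng.random() < fragment_error:
                    base = _mutate_base(base, rng)
                n_mates = 2 if rng.random() < overlap_fraction else 1
                obs = []
                for _ in range(n_mates):
                    b = base
                    if read_error > 0 and rng.random() < read_error:
                        b = _mutate_base(b, rng)
                    obs.append((b, qual))
                frags.append(FragmentObservation(f"frag{i}_{j}_{f}", obs))
            pileups[(i, j)] = SitePileup(
                truth.snp_ids[i], truth.sample_ids[j], ref, alt, frags
            )
    return PileupSet(
        snp_ids=list(truth.snp_ids),
        sample_ids=list(truth.sample_ids),
        alleles=list(panel.alleles),
        pileups=pileups,
    )


def _mutate_base(base: str, rng: np.random.Generator) -> str:
    others = [b for b in BASES if b != base]
    return others[rng.integers(0, 3)]


def downsample(pileups: PileupSet, keep_fraction: float, seed: int = 0) -> PileupSet:
    """Thin pileups by whole fragments, each kept with prob keep_fraction.

    Both mates of a fragment are kept or dropped together, mirroring
    read-group down-sampling of paired data.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict = {}
    for key in sorted(pileups.pileups):
        p = pileups.pileups[key]
        kept = [f for f in p.fragments if rng.random() < keep_fraction]
        if kept:
            out[key] = SitePileup(p.snp_id, p.sample_id, p.ref_base, p.alt_base, kept)
    return PileupSet(
        snp_ids=list(pileups.snp_ids),
        sample_ids=list(pileups.sample_ids),
        alleles=list(pileups.alleles),
        pileups=out,
    )


def default_cluster_template(scale: float = 1.0, noise: float = 0.02) -> ClusterParams:
    """Canonical well-separated 3-cluster template on the (a, b) plane.

    Class 0 (hom-ref) loads on the a channel, class 2 (hom-alt) on b, so the
    contrast a - b decreases with the non-reference allele count.
    """
    means = scale * np.array([[2.0, 0.2], [1.1, 1.1], [0.2, 2.0]])
    covs = np.stack([noise * scale**2 * np.eye(2)] * 3)
    priors = np.full(3, 1.0 / 3.0)
    return ClusterParams(means, covs, priors)


def simulate_intensities(
    truth: SyntheticTruth,
    template: ClusterParams | None = None,
    noise_scale: float = 1.0,
    artifact_config: dict | None = None,
    mean_jitter: float = 0.05,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw per-sample 2-channel intensities from each SNP's true clusters.

    Each SNP's cluster means start at the template (plus a small per-SNP
    jitter) and are then distorted per its artifact class:

    * ``cluster_shift`` — one class mean displaced toward a neighbouring
      class mean (by a fraction ``shift`` of the distance between them), the
      compressed-contrast failure that makes intensity-only clustering
      mis-assign samples,
    * ``merged_clusters`` — het mean moved onto a homozygote mean,
    * ``null_probe`` — all three means collapse to one point (the array sees
      the SNP as monomorphic however variable the cohort is).

    ``artifact_config`` maps artifact class to a dict with at least
    ``fraction`` (of SNPs to plant); ``cluster_shift`` also accepts ``shift``
    (fraction of the between-mean distance, default 0.85). Returns an
    (S, N, 2) array (NaN where
    missing) and stores the per-SNP true ClusterParams and artifact labels on
    ``truth``.
    """
    if template is None:
        template = default_cluster_template()
    artifact_config = dict(artifact_config or {})
    for cls in artifact_config:
        if cls not in ARTIFACT_CLASSES or cls == "none":
            raise ValueError(f"unknown artifact class {cls!r}")

    rng = np.random.default_rng(seed)
    S, N = truth.n_snps, truth.n_samples

    labels = np.full(S, "none", dtype=object)
    order = rng.permutation(S)
    cursor = 0
    for cls, cfg in artifact_config.items():
        k = int(round(cfg.get("fraction", 0.0) * S))
        labels[order[cursor : cursor + k]] = cls
        cursor += k

    intensities = np.empty((S, N, 2))
    params: list = []
    for i in range(S):
        means = template.means + rng.normal(0.0, mean_jitter, size=(3, 2))
        covs = template.covs * noise_scale
        if labels[i] == "cluster_shift":
            g = rng.integers(0, 3)
            neighbour = 1 if g != 1 else rng.choice([0, 2])
            shift = artifact_config["cluster_shift"].get("shift", 0.85)
            means[g] = means[g] + shift * (means[neighbour] - means[g])
        elif labels[i] == "merged_clusters":
            means[1] = means[rng.choice([0, 2])]
        elif labels[i] == "null_probe":
            means[:] = means[rng.integers(0, 3)]
        p = ClusterParams(means, covs, template.priors.copy())
        params.append(p)
        for g in range(3):
            idx = np.flatnonzero(truth.genotypes[i] == g)
            if idx.size == 0:
                continue
            if noise_scale == 0:
                intensities[i, idx] = means[g]
            else:
                intensities[i, idx] = rng.multivariate_normal(
                    means[g], covs[g], size=idx.size
                )
    if missing_rate > 0:
        mask = rng.random((S, N)) < missing_rate
        intensities[mask] = np.nan

    truth.artifact_labels = labels
    truth.true_cluster_params = params
    return intensities


def simulate_error_covariates(
    truth: SyntheticTruth,
    enrichment_spec: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-SNP error-mode covariates with class-dependent distributions.

    ``enrichment_spec`` maps covariate name to a dict::

        {"kind": "binary", "rates": {class_label: rate, ..., "default": r}}
        {"kind": "continuous", "means": {...same...}, "sd": 1.0}

    Class labels refer to ``truth.artifact_labels`` (label "default" covers
    any class not named). Binary covariates are Bernoulli draws, continuous
    covariates normal draws. The spec is recorded on the truth object so
    enrichment-recovery tests can check against it.
    """
    if truth.artifact_labels is None:
        truth.artifact_labels = np.full(truth.n_snps, "none", dtype=object)
    rng = np.random.default_rng(seed)
    labels = truth.artifact_labels
    cols: dict = {}
    for name, spec in enrichment_spec.items():
        kind = spec.get("kind")
        if kind == "binary":
            rates = spec["rates"]
            p = np.array([rates.get(l, rates.get("default", 0.0)) for l in labels])
            cols[name] = (rng.random(truth.n_snps) < p).astype(int)
        elif kind == "continuous":
            means = spec["means"]
            sd = spec.get("sd", 1.0)
            mu = np.array([means.get(l, means.get("default", 0.0)) for l in labels])
            cols[name] = rng.normal(mu, sd)
        else:
            raise ValueError(f"covariate {name!r} must be binary or continuous")
    table = pd.DataFrame(cols, index=truth.snp_ids)
    truth.covariates = table
    truth.covariate_spec = enrichment_spec
    return table
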
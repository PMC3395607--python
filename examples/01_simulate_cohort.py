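"""Simulate a synthetic cohort: LD haplotypes, genotypes, reads, intensities.

The generator builds the statistical world the joint caller assumes: a
haplotype panel with linkage disequilibrium (mosaic copying of founders),
diploid samples drawn from it, Poisson low-coverage pileups in which
library-prep errors are shared by overlapping mates, and three-cluster
array intensities.
"""

import numpy as np

import jointgt as jg

panel = jg.simdata.simulate_panel(
    n_founders=8, n_haplotypes=120, n_snps=150,
    recomb_prob=0.02, mutation_prob=0.001, seed=1,
)
truth = jg.simdata.simulate_cohort(panel, n_samples=60, seed=2)
piles = jg.simdata.simulate_reads(
    truth, mean_coverage=1.0, overlap_fraction=0.2, seed=3
)
inten = jg.simdata.simulate_intensities(truth, seed=4)

print(f"panel: {panel.n_haplotypes} haplotypes x {panel.n_snps} SNPs "
      f"(monomorphic columns dropped)")
print(f"cohort genotype matrix: {truth.genotypes.shape}, "
      f"allele frequency mean {truth.genotypes.mean() / 2:.3f}")
depth = piles.depth_matrix()
print(f"pileups: mean depth {depth.mean():.2f} reads/site "
      f"(target 1.0), {int((depth == 0).sum())} site-samples with no coverage")
print(f"intensities: {inten.shape} (samples cluster by genotype on the a/b plane)")

# adjacent SNPs are correlated (that LD is what imputation exploits)
h = panel.haplotypes.astype(float)

def mean_r2(lag):
    vals = []
    for i in range(0, panel.n_snps - lag, 3):
        r = np.corrcoef(h[:, i], h[:, i + lag])[0, 1]
        vals.append(r * r)
    return float(np.nanmean(vals))

print(f"mean r^2: adjacent SNPs {mean_r2(1):.3f}, "
      f"50 SNPs apart {mean_r2(50):.3f}")
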
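"""LD-based imputation: recovering genotypes nobody directly observed.

The phasing / imputation engine consumes per-site genotype likelihoods and
returns LD-aware posteriors via an iterative haploid-copying HMM. Here 10%
of entries get completely flat likelihoods (no data); the engine recovers
them from linkage with the surrounding sites.
"""

import numpy as np

import jointgt as jg
from jointgt import ldimpute

panel = jg.simdata.simulate_panel(6, 100, 100, recomb_prob=0.02,
                                  mutation_prob=0.001, seed=21)
truth = jg.simdata.simulate_cohort(panel, 50, seed=22)
S, N = truth.n_snps, truth.n_samples

# perfect data everywhere except a 10% random mask with no information
ll = np.full((S, N, 3), -30.0)
np.put_along_axis(ll, truth.genotypes[:, :, None].astype(int), 0.0, axis=2)
rng = np.random.default_rng(23)
mask = rng.random((S, N)) < 0.1
ll[mask] = 0.0
gl = jg.GenotypeLikelihoodMatrix(ll, panel.positions, panel.alleles,
                                 truth.snp_ids, truth.sample_ids)

post = ldimpute.phase_impute(gl, n_iterations=20, seed=24).posteriors
flat = ldimpute.posterior_without_ld(gl).posteriors

tg = truth.genotypes[:, :, None].astype(int)
with_ld = np.take_along_axis(post, tg, 2)[:, :, 0][mask].mean()
no_ld = np.take_along_axis(flat, tg, 2)[:, :, 0][mask].mean()
acc = (post.argmax(axis=2) == truth.genotypes)[mask].mean()

print(f"masked entries: {int(mask.sum())} of {S * N}")
print(f"mean posterior of the true genotype at masked entries: {with_ld:.3f}")
print(f"same quantity without LD (frequency prior only):        {no_ld:.3f}")
print(f"argmax accuracy at masked entries: {acc:.3f}")
print("the gap is pure LD information: nothing was observed at those entries")
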
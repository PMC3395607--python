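"""Fit the per-SNP three-class intensity mixture and read off genotypes.

Each SNP's two-channel array intensities form three clusters (one per
genotype). The model is a bivariate-Gaussian mixture: class means,
covariances and mixing weights are fit by EM, anchored at a prior template
so the class index stays tied to the non-reference allele count.
"""

import numpy as np

import jointgt as jg
from jointgt import intensity

panel = jg.simdata.simulate_panel(8, 120, 50, seed=11)
truth = jg.simdata.simulate_cohort(panel, 400, seed=12)
inten = jg.simdata.simulate_intensities(truth, seed=13)

template = jg.simdata.default_cluster_template()
i = 0
params, trace = intensity.init_clusters(inten[i], template)

print(f"SNP {truth.snp_ids[i]}: EM converged in {len(trace)} iterations "
      f"(log-likelihood {trace[0]:.1f} -> {trace[-1]:.1f})")
for g in range(3):
    true_mean = truth.true_cluster_params[i].means[g]
    print(f"  class {g}: fitted mean ({params.means[g][0]:.2f}, {params.means[g][1]:.2f})"
          f"  true ({true_mean[0]:.2f}, {true_mean[1]:.2f})"
          f"  prior {params.priors[g]:.2f}")

# genotype by maximum class density
lik = intensity.log_likelihood_matrix(inten[i], params)
acc = (lik.argmax(axis=1) == truth.genotypes[i]).mean()
print(f"array-only genotype accuracy at this SNP: {acc:.3f} "
      f"(clusters are well separated, so intensities alone suffice here)")
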
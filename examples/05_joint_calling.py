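"""Joint genotype calling: array + sequence + imputation beats each alone.

The outer EM combines per-SNP intensity likelihoods with sequence genotype
likelihoods (naive Bayes), runs phasing / imputation across SNPs and
samples, re-estimates the intensity clusters from the posteriors, and
iterates (3 rounds). Planted array artifacts (failed probes) show why the
combination matters: sequence evidence rescues SNPs the array gets wrong.
"""

import numpy as np

import jointgt as jg
from jointgt import metrics

panel = jg.simdata.simulate_panel(8, 150, 120, recomb_prob=0.02,
                                  mutation_prob=0.001, seed=31)
truth = jg.simdata.simulate_cohort(panel, 80, seed=32)
piles = jg.simdata.simulate_reads(truth, mean_coverage=2.0,
                                  overlap_fraction=0.2, seed=33)
inten = jg.simdata.simulate_intensities(
    truth, artifact_config={"null_probe": {"fraction": 0.05}}, seed=34
)

runs = {
    "joint": jg.JointCallConfig(seed=42),
    "sequence-only": jg.JointCallConfig(use_array=False, seed=42),
    "array-only": jg.JointCallConfig(use_sequence=False, seed=42),
}
gold = truth.genotypes
art = truth.artifact_labels == "null_probe"
print(f"cohort: {truth.n_samples} samples x {truth.n_snps} SNPs at 2x, "
      f"{int(art.sum())} failed probes planted\n")
for name, cfg in runs.items():
    res = jg.joint_call(inten if cfg.use_array else None,
                        pileups=piles, config=cfg)
    sens = metrics.nonref_sensitivity(res.calls, gold)
    spec = metrics.nonref_specificity(res.calls, gold)
    m = np.broadcast_to(art[:, None], gold.shape)
    sens_art = metrics.nonref_sensitivity(res.calls, gold, m)
    print(f"{name:14s} sens={sens:.3f} spec={spec:.3f} "
          f"| sens at failed probes: {sens_art:.3f}")
print("\njoint calls match the array where it works and the sequence where")
print("the probe failed; neither single technology manages both")
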
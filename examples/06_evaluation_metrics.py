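"""Non-reference sensitivity / specificity with stratification.

Sensitivity = fraction of non-reference gold-standard genotypes called
identically (no-calls count against it); specificity = fraction of
non-reference calls that match the gold standard (no-calls excluded).
Strata: minor-allele-frequency bins with frequency taken from the non-test
samples (so "private" variants are invisible to imputation), zygosity, and
strand-ambiguous (A/T, C/G) site removal.
"""

import jointgt as jg
from jointgt import metrics

panel = jg.simdata.simulate_panel(8, 200, 150, recomb_prob=0.02,
                                  mutation_prob=0.01, seed=41)
truth = jg.simdata.simulate_cohort(panel, 100, seed=42)
piles = jg.simdata.simulate_reads(truth, mean_coverage=2.0, seed=43)
inten = jg.simdata.simulate_intensities(truth, seed=44)

res = jg.joint_call(inten, pileups=piles, config=jg.JointCallConfig(seed=45))

# evaluate the first sample against the truth, frequencies from the rest
report = metrics.stratify(
    res.calls.genotypes[:, :1],
    truth.genotypes[:, :1],
    cohort_genotypes=truth.genotypes,
    exclude_samples=[0],
    alleles=panel.alleles,
)
print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nrare and private variants are the hard cases: the test sample may be")
print("the only carrier, so LD with the rest of the cohort cannot supply them")
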
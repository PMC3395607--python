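"""Non-reference sensitivity / specificity and stratified evaluation.

Definitions (gold = gold-standard genotypes, calls = evaluated call set,
"non-reference" = genotype in {1, 2}):

* sensitivity — fraction of non-reference *gold* genotypes whose call exists
  and is identical; no-calls count against sensitivity.
* specificity — fraction of non-reference *called* genotypes identical to
  gold; no-calls are excluded from the denominator.

"Identical" means exact 0/1/2 equality (het != hom-alt). Entries with no
gold genotype are ignored. Sites with strand-ambiguous alleles (A/T or C/G)
are excluded by default from every metric entry point. Empty denominators
yield ``None`` (undefined), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CallSet, NO_CALL

DEFAULT_MAF_BINS = ((0.0, 0.005), (0.005, 0.05), (0.05, 0.5))

AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass
class StratumMetrics:
    sens: float | None
    spec: float | None
    n_gold_nonref: int
    n_called_nonref: int
    n_sens_match: int
    n_spec_match: int


@dataclass
class MetricsReport:
    sens: float | None
    spec: float | None
    n_gold_nonref: int
    n_called_nonref: int
    strata: dict = field(default_factory=dict)
    frequency_source: str = "gold"

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "stratum": "all",
                "sens": self.sens,
                "spec": self.spec,
                "n_gold_nonref": self.n_gold_nonref,
                "n_called_nonref": self.n_called_nonref,
            }
        ]
        for name, s in self.strata.items():
            rows.append(
                {
                    "stratum": name,
                    "sens": s.sens,
                    "spec": s.spec,
                    "n_gold_nonref": s.n_gold_nonref,
                    "n_called_nonref": s.n_called_nonref,
                }
            )
        return pd.DataFrame(rows)


def _as_genotypes(calls) -> np.ndarray:
    if isinstance(calls, CallSet):
        return calls.genotypes
    return np.asarray(calls)


def filter_ambiguous(alleles) -> np.ndarray:
    """Boolean keep-mask: False for A/T and C/G (strand-ambiguous) sites."""
    keep = np.ones(len(alleles), dtype=bool)
    for i, (ref, alt) in enumerate(alleles):
        if {ref, alt} in AMBIGUOUS_PAIRS:
            keep[i] = False
    return keep


def _counts(calls: np.ndarray, gold: np.ndarray, mask: np.ndarray) -> StratumMetrics:
    gold_valid = mask & (gold != NO_CALL)
    gold_nonref = gold_valid & (gold > 0)
    called = calls != NO_CALL
    call_nonref = gold_valid & called & (calls > 0)
    match = calls == gold

    n_gold = int(gold_nonref.sum())
    n_called = int(call_nonref.sum())
    n_sens = int((gold_nonref & called & match).sum())
    n_spec = int((call_nonref & match).sum())
    return StratumMetrics(
        sens=(n_sens / n_gold) if n_gold else None,
        spec=(n_spec / n_called) if n_called else None,
        n_gold_nonref=n_gold,
        n_called_nonref=n_called,
        n_sens_match=n_sens,
        n_spec_match=n_spec,
    )


def nonref_sensitivity(calls, gold, mask=None) -> float | None:
    """Fraction of non-reference gold genotypes with identical calls."""
    c, g = _as_genotypes(calls), _as_genotypes(gold)
    m = np.ones(g.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    return _counts(c, g, m).sens


def nonref_specificity(calls, gold, mask=None) -> float | None:
    """Fraction of non-reference calls that match the gold standard."""
    c, g = _as_genotypes(calls), _as_genotypes(gold)
    m = np.ones(g.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    return _counts(c, g, m).spec


def normalized_metric(
    joint_value_offarray: float,
    seq_value_offarray: float,
    seq_value_allsites: float,
) -> float | None:
    """Normalised off-array metric: (joint/seq at off-array sites) x seq at all sites.

    Makes values comparable across arrays that type different site sets.
    Undefined (None) when the sequence-only off-array value is zero.
    """
    if seq_value_offarray == 0:
        return None
    return (joint_value_offarray / seq_value_offarray) * seq_value_allsites


def site_frequencies(cohort_genotypes: np.ndarray, exclude_samples=None) -> np.ndarray:
    """Non-reference allele frequency per SNP from cohort genotypes.

    ``exclude_samples`` removes the evaluated (test) sample(s) so private
    variants — frequency 0 in the non-test samples — are identifiable.
    """
    g = np.asarray(cohort_genotypes, dtype=float)
    if exclude_samples is not None:
        keep = np.ones(g.shape[1], dtype=bool)
        keep[np.asarray(exclude_samples)] = False
        g = g[:, keep]
    valid = g >= 0
    n = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freq = np.where(valid, g, 0.0).sum(axis=1) / np.maximum(2 * n, 1)
    freq[n == 0] = np.nan
    return freq


def stratify(
    calls,
    gold,
    cohort_genotypes=None,
    exclude_samples=None,
    alleles=None,
    positions=None,
    coding_intervals=None,
    maf_bins=DEFAULT_MAF_BINS,
    by_zygosity: bool = True,
    drop_ambiguous: bool = True,
) -> MetricsReport:
    """Full metrics report with MAF / private / zygosity / coding strata.

    Frequencies come from ``cohort_genotypes`` (true genotypes when
    available) with ``exclude_samples`` removed; variants absent from all
    non-test samples form the "private" stratum. ``coding_intervals`` is a
    list of (start, end) 0-based half-open intervals over ``positions``.
    Empty strata are reported with undefined (None) metrics, never dropped.
    """
    c, g = _as_genotypes(calls), _as_genotypes(gold)
    S = g.shape[0]
    site_mask = np.ones(S, dtype=bool)
    if drop_ambiguous and alleles is not None:
        site_mask &= filter_ambiguous(alleles)
    base_mask = np.broadcast_to(site_mask[:, None], g.shape).copy()

    overall = _counts(c, g, base_mask)
    report = MetricsReport(
        sens=overall.sens,
        spec=overall.spec,
        n_gold_nonref=overall.n_gold_nonref,
        n_called_nonref=overall.n_called_nonref,
        frequency_source="cohort" if cohort_genotypes is not None else "calls",
    )

    if cohort_genotypes is None:
        cohort_genotypes = np.where(c == NO_CALL, -1, c)
    freq = site_frequencies(cohort_genotypes, exclude_samples)
    maf = np.minimum(freq, 1.0 - freq)

    private = freq == 0.0
    report.strata["private"] = _counts(c, g, base_mask & private[:, None])
    for lo, hi in maf_bins:
        label = f"maf({lo:g},{hi:g}]"
        sel = (maf > lo) & (maf <= hi) & ~private
        report.strata[label] = _counts(c, g, base_mask & sel[:, None])

    if by_zygosity:
        report.strata["het"] = _counts(c, g, base_mask & (g == 1))
        report.strata["hom_nonref"] = _counts(c, g, base_mask & (g == 2))

    if coding_intervals is not None and positions is not None:
        pos = np.asarray(positions)
        coding = np.zeros(S, dtype=bool)
        for start, end in coding_intervals:
            coding |= (pos >= start) & (pos < end)
        report.strata["coding"] = _counts(c, g, base_mask & coding[:, None])
        report.strata["noncoding"] = _counts(c, g, base_mask & ~coding[:, None])
    return report
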
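"""Disputed-SNP discovery, classification, and error-mode statistics.

A SNP is *disputed* when array-based and sequence-based genotype calls
disagree for at least a threshold fraction (default 10%, alternate 25%) of
the samples called by both technologies. Joint calls arbitrate each dispute:
if they closely match the sequence calls the SNP is an apparent array error,
if they closely match the array calls an apparent sequence error, otherwise
unresolved.

Error-mode covariates are tested for enrichment between the two apparent-
error classes (Fisher's exact test for binary modes, Kruskal-Wallis for
continuous ones), and individual disputed SNPs are *characterized* by a mode
when a binary flag is 1 or when the log10 likelihood ratio (LOD) of the
error-class kernel density to the non-disputed density exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import CallSet, NO_CALL

DEFAULT_DISPUTE_THRESHOLD = 0.10
DEFAULT_LOD_THRESHOLD = 2.0
DEFAULT_CONCORDANCE_CUTOFF = 0.9
MIN_KDE_POINTS = 20

AGREED = "agreed"
DISPUTED = "disputed"
APPARENT_ARRAY_ERROR = "apparent_array_error"
APPARENT_SEQUENCE_ERROR = "apparent_sequence_error"
UNRESOLVED = "unresolved"


@dataclass
class DisputeRecord:
    snp_id: str
    discordance_rate: float | None  # None when no co-called samples
    dispute_class: str  # agreed | disputed
    resolution: str | None = None  # only set when disputed


def _genotypes(calls) -> np.ndarray:
    return calls.genotypes if isinstance(calls, CallSet) else np.asarray(calls)


def discordance_rates(array_calls, seq_calls) -> np.ndarray:
    """Per-SNP fraction of co-called samples with differing genotypes.

    The denominator counts samples called by *both* technologies; SNPs with
    no co-called sample get NaN (undefined).
    """
    a, s = _genotypes(array_calls), _genotypes(seq_calls)
    if a.shape != s.shape:
        raise ValueError("call sets must share the SNP x sample universe")
    both = (a != NO_CALL) & (s != NO_CALL)
    n = both.sum(axis=1)
    disagree = (both & (a != s)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rates = np.where(n > 0, disagree / np.maximum(n, 1), np.nan)
    return rates


def find_disputes(
    rates, snp_ids=None, threshold: float = DEFAULT_DISPUTE_THRESHOLD
) -> list:
    """Classify each SNP as agreed or disputed (rate >= threshold)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    rates = np.asarray(rates, dtype=float)
    if snp_ids is None:
        snp_ids = [f"snp{i:05d}" for i in range(len(rates))]
    records = []
    for sid, r in zip(snp_ids, rates):
        if np.isnan(r):
            records.append(DisputeRecord(sid, None, AGREED))
        else:
            cls = DISPUTED if r >= threshold else AGREED
            records.append(DisputeRecord(sid, float(r), cls))
    return records


def _concordance(x: np.ndarray, y: np.ndarray) -> float | None:
    both = (x != NO_CALL) & (y != NO_CALL)
    n = int(both.sum())
    if n == 0:
        return None
    return float((x[both] == y[both]).sum() / n)


def classify_disputes(
    disputes: list,
    joint_calls,
    seq_calls,
    array_calls,
    concordance_cutoff: float = DEFAULT_CONCORDANCE_CUTOFF,
) -> list:
    """Resolve each disputed SNP by which technology the joint calls side with.

    Apparent array error: joint-vs-sequence concordance strictly exceeds
    joint-vs-array concordance and reaches ``concordance_cutoff``; apparent
    sequence error is the mirror case; anything else (including SNPs whose
    joint calls are all no-calls) is unresolved.
    """
    j = _genotypes(joint_calls)
    s = _genotypes(seq_calls)
    a = _genotypes(array_calls)
    out = []
    for i, rec in enumerate(disputes):
        rec = DisputeRecord(rec.snp_id, rec.discordance_rate, rec.dispute_class)
        if rec.dispute_class == DISPUTED:
            c_seq = _concordance(j[i], s[i])
            c_arr = _concordance(j[i], a[i])
            if c_seq is None or c_arr is None:
                rec.resolution = UNRESOLVED
            elif c_seq > c_arr and c_seq >= concordance_cutoff:
                rec.resolution = APPARENT_ARRAY_ERROR
            elif c_arr > c_seq and c_arr >= concordance_cutoff:
                rec.resolution = APPARENT_SEQUENCE_ERROR
            else:
                rec.resolution = UNRESOLVED
        out.append(rec)
    return out


def binary_enrichment(flags, classes) -> float | None:
    """Two-sided Fisher exact p for a binary error mode between two classes.

    ``classes`` holds exactly two distinct labels; returns None (undefined)
    when either class is empty.
    """
    flags = np.asarray(flags).astype(int)
    classes = np.asarray(classes)
    labels = np.unique(classes)
    if len(labels) != 2:
        raise ValueError("binary enrichment requires exactly two classes")
    table = np.empty((2, 2), dtype=int)
    for r, lab in enumerate(labels):
        sel = classes == lab
        if sel.sum() == 0:
            return None
        table[r, 0] = int((flags[sel] == 1).sum())
        table[r, 1] = int((flags[sel] == 0).sum())
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


#: All two-group samples this small get an exact permutation p-value; the
#: chi-square reference for the H statistic is unreliable below ~6 per group.
EXACT_KRUSKAL_MAX_GROUP = 6


def continuous_enrichment(values, classes) -> float | None:
    """Kruskal-Wallis p for a continuous error mode across classes.

    Tie-corrected H with a chi-square reference; identical values across all
    groups give H = 0, p = 1. Two-group comparisons with at most
    ``EXACT_KRUSKAL_MAX_GROUP`` values per group use the exact permutation
    distribution of H instead of the asymptotic reference.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    groups = [values[classes == lab] for lab in np.unique(classes)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return None
    if np.all(np.concatenate(groups) == np.concatenate(groups)[0]):
        return 1.0
    if len(groups) == 2 and max(len(g) for g in groups) <= EXACT_KRUSKAL_MAX_GROUP:
        return _exact_kruskal_two_groups(groups[0], groups[1])
    return float(stats.kruskal(*groups)[1])


def _exact_kruskal_two_groups(x: np.ndarray, y: np.ndarray) -> float:
    """Exact permutation p for the two-group Kruskal-Wallis H statistic."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    h_obs = stats.kruskal(x, y)[0]
    count = total = 0
    for idx in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        h = stats.kruskal(pooled[sel], pooled[~sel])[0]
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def _gaussian_kde_fixed_bw(data: np.ndarray, bandwidth: float):
    """1-D Gaussian KDE with an absolute bandwidth (scipy uses a factor)."""
    data = np.asarray(data, dtype=float)
    sd = data.std(ddof=1)
    if sd == 0:
        sd = 1.0
    return stats.gaussian_kde(data, bw_method=bandwidth / sd)


def silverman_bandwidth(data: np.ndarray) -> float:
    data = np.asarray(data, dtype=float)
    n = len(data)
    sd = data.std(ddof=1)
    if sd == 0 or n < 2:
        return 1.0
    return 1.06 * sd * n ** (-1 / 5)


def characterize(
    values,
    class_labels,
    kind: str = "continuous",
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
    min_reference_points: int = MIN_KDE_POINTS,
) -> np.ndarray:
    """Flag SNPs characterized by an error mode.

    ``class_labels`` per SNP: "non_disputed", or an apparent-error class.
    Binary modes flag value == 1. Continuous modes fit Gaussian-kernel
    densities to the non-disputed SNPs (f_N, Silverman bandwidth) and to each
    apparent-error class (f_E, same bandwidth) and flag a disputed SNP when
    log10(f_E(v) / f_N(v)) > lod_threshold; a numerically zero f_N(v) counts
    as an infinite LOD (flagged).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(class_labels)
    flags = np.zeros(len(values), dtype=bool)
    if kind == "binary":
        disputed = labels != "non_disputed"
        flags[disputed] = values[disputed] == 1
        return flags
    if kind != "continuous":
        raise ValueError("kind must be 'binary' or 'continuous'")

    ref = values[labels == "non_disputed"]
    if len(ref) < min_reference_points:
        raise ValueError(
            f"need >= {min_reference_points} non-disputed SNPs to fit the "
            "reference density"
        )
    bw = silverman_bandwidth(ref)
    kde_ref = _gaussian_kde_fixed_bw(ref, bw)
    for cls in np.unique(labels):
        if cls == "non_disputed":
            continue
        sel = labels == cls
        grp = values[sel]
        if len(grp) == 0:
            continue
        kde_err = (
            _gaussian_kde_fixed_bw(grp, bw)
            if len(grp) > 1
            else _gaussian_kde_fixed_bw(np.repeat(grp, 2), bw)
        )
        f_e = kde_err(values[sel])
        f_n = kde_ref(values[sel])
        with np.errstate(divide="ignore"):
            lod = np.where(
                f_n > 0, np.log10(np.maximum(f_e, 1e-320)) - np.log10(f_n), np.inf
            )
        flags[sel] = lod > lod_threshold
    return flags


def error_mode_tests(covariates, classes, kinds: dict) -> dict:
    """Run the per-mode enrichment test battery.

    ``covariates`` is a DataFrame (SNPs x modes) restricted to disputed SNPs,
    ``classes`` the apparent-error class per row, ``kinds`` maps mode name to
    "binary" or "continuous". Returns {mode: p_value}.
    """
    out = {}
    for name in covariates.columns:
        kind = kinds.get(name, "continuous")
        col = covariates[name].to_numpy()
        if kind == "binary":
            out[name] = binary_enrichment(col, classes)
        else:
            out[name] = continuous_enrichment(col, classes)
    return out
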
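"""Readers and writers for every external format.

VCF (via pysam) is the single genotype interchange format: GL/PL in, GT / GQ
/ GP / PL out, 1-based positions. Tabular data (pileups, intensities,
covariates, cluster parameters) travel as documented TSVs; BED intervals are
0-based half-open. All internal coordinates are 0-based; the 1-based
conversion is confined to this module. Every writer has a matching reader
and round-trips.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
import pysam

from .containers import (
    CallSet,
    ClusterParams,
    FragmentObservation,
    GenotypeLikelihoodMatrix,
    NO_CALL,
    PileupSet,
    SitePileup,
)

DEFAULT_CHROM = "20"


class FormatError(ValueError):
    """A file violated its documented schema."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _vcf_header(sample_ids, contig=DEFAULT_CHROM, extra_meta=None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=2_000_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    header.formats.add("GP", 3, "Float", "Genotype posterior probabilities")
    header.formats.add("GL", 3, "Float", "Log10-scaled genotype likelihoods")
    header.formats.add("PL", 3, "Integer", "Phred-scaled genotype likelihoods")
    for key, value in (extra_meta or {}).items():
        header.add_meta(key, value=str(value))
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def _gt_tuple(g: int):
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}.get(g, (None, None))


def write_genotypes_vcf(
    path,
    genotypes: np.ndarray,
    positions,
    alleles,
    snp_ids,
    sample_ids,
    contig: str = DEFAULT_CHROM,
) -> None:
    """Write plain GT records (the simulator's truth output)."""
    header = _vcf_header(sample_ids, contig)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, sid in enumerate(snp_ids):
            rec = vf.new_record(
                contig=contig,
                start=int(positions[i]),  # pysam start is 0-based
                stop=int(positions[i]) + 1,
                alleles=(alleles[i][0], alleles[i][1]),
                id=sid,
            )
            for j, sample in enumerate(sample_ids):
                rec.samples[sample]["GT"] = _gt_tuple(int(genotypes[i, j]))
            vf.write(rec)


def read_genotypes_vcf(path) -> tuple:
    """Read GT records -> (genotypes, positions, alleles, snp_ids, sample_ids)."""
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        genotypes, positions, alleles, snp_ids = [], [], [], []
        for rec in vf:
            if len(rec.alleles) != 2:
                continue
            row = []
            for sid in sample_ids:
                gt = rec.samples[sid]["GT"]
                if gt is None or None in gt:
                    row.append(NO_CALL)
                else:
                    row.append(int(sum(gt)))
            genotypes.append(row)
            positions.append(rec.start)
            alleles.append((rec.alleles[0], rec.alleles[1]))
            snp_ids.append(rec.id or f"snp{len(snp_ids):05d}")
    return (
        np.asarray(genotypes, dtype=np.int8),
        np.asarray(positions, dtype=np.int64),
        alleles,
        snp_ids,
        sample_ids,
    )


def write_gl_vcf(path, gl: GenotypeLikelihoodMatrix, contig: str = DEFAULT_CHROM) -> None:
    """Write per-sample GL (log10) and PL fields for each biallelic site."""
    header = _vcf_header(gl.sample_ids, contig)
    log10 = gl.log_likelihoods / np.log(10.0)
    log10 = log10 - log10.max(axis=2, keepdims=True)
    pl = np.minimum(np.round(-10.0 * log10), 9999).astype(int)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, sid in enumerate(gl.snp_ids):
            rec = vf.new_record(
                contig=contig,
                start=int(gl.positions[i]),
                stop=int(gl.positions[i]) + 1,
                alleles=(gl.alleles[i][0], gl.alleles[i][1]),
                id=sid,
            )
            for j, sample in enumerate(gl.sample_ids):
                rec.samples[sample]["GL"] = tuple(float(x) for x in log10[i, j])
                rec.samples[sample]["PL"] = tuple(int(x) for x in pl[i, j])
            vf.write(rec)


def read_vcf_genotype_likelihoods(path, prefer: str = "GL") -> GenotypeLikelihoodMatrix:
    """Read GL (log10) or PL (Phred integer) fields into a GL matrix.

    PL is converted via likelihood = 10^(-PL/10) and max-normalised.
    Multi-allelic and non-SNP records are skipped (counted); a record with
    neither GL nor PL raises :class:`FormatError` naming the record.
    """
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        has_gl = "GL" in vf.header.formats
        has_pl = "PL" in vf.header.formats
        rows, positions, alleles, snp_ids = [], [], [], []
        n_skipped = 0
        for rec in vf:
            if len(rec.alleles) != 2 or any(len(a) != 1 for a in rec.alleles):
                n_skipped += 1
                continue
            row = np.zeros((len(sample_ids), 3))
            for j, sid in enumerate(sample_ids):
                fmt = rec.samples[sid]
                gl_ok = has_gl and fmt.get("GL") is not None
                pl_ok = has_pl and fmt.get("PL") is not None
                if prefer == "GL" and gl_ok or (gl_ok and not pl_ok):
                    vals = np.asarray(fmt["GL"], dtype=float) * np.log(10.0)
                elif pl_ok:
                    vals = -np.asarray(fmt["PL"], dtype=float) / 10.0 * np.log(10.0)
                else:
                    raise FormatError(
                        f"record {rec.id or rec.pos} has neither GL nor PL"
                    )
                row[j] = vals - vals.max()
            rows.append(row)
            positions.append(rec.start)
            alleles.append((rec.alleles[0], rec.alleles[1]))
            snp_ids.append(rec.id or f"snp{len(snp_ids):05d}")
    if not rows:
        raise FormatError(f"no usable biallelic SNP records in {path}")
    return GenotypeLikelihoodMatrix(
        log_likelihoods=np.stack(rows),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        snp_ids=snp_ids,
        sample_ids=sample_ids,
    )


def write_calls_vcf(
    path,
    calls: CallSet,
    positions,
    alleles,
    snp_ids,
    sample_ids,
    contig: str = DEFAULT_CHROM,
    provenance: dict | None = None,
) -> None:
    """Emit GT / GQ / GP / PL; no-calls as ./.; header records provenance."""
    meta = {}
    if provenance:
        blob = json.dumps(provenance, sort_keys=True)
        meta["jointgt_config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
        if "seed" in provenance:
            meta["jointgt_seed"] = provenance["seed"]
    header = _vcf_header(sample_ids, contig, extra_meta=meta)
    post = calls.posteriors
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, sid in enumerate(snp_ids):
            rec = vf.new_record(
                contig=contig,
                start=int(positions[i]),
                stop=int(positions[i]) + 1,
                alleles=(alleles[i][0], alleles[i][1]),
                id=sid,
            )
            for j, sample in enumerate(sample_ids):
                fmt = rec.samples[sample]
                fmt["GT"] = _gt_tuple(int(calls.genotypes[i, j]))
                fmt["GQ"] = int(round(calls.gq[i, j]))
                if post is not None:
                    p = np.maximum(post[i, j], 1e-300)
                    fmt["GP"] = tuple(float(x) for x in post[i, j])
                    pl = -10.0 * np.log10(p)
                    pl -= pl.min()
                    fmt["PL"] = tuple(int(round(min(x, 9999))) for x in pl)
            vf.write(rec)


def read_calls_vcf(path) -> tuple:
    """Read a calls VCF -> (CallSet, positions, alleles, snp_ids, sample_ids)."""
    genotypes, positions, alleles, snp_ids, sample_ids = read_genotypes_vcf(path)
    gq = np.zeros(genotypes.shape)
    post = None
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        has_gp = "GP" in vf.header.formats
        if has_gp:
            post = np.full((len(snp_ids), len(samples), 3), 1.0 / 3.0)
        for i, rec in enumerate(vf):
            for j, sid in enumerate(samples):
                fmt = rec.samples[sid]
                if fmt.get("GQ") is not None:
                    gq[i, j] = float(fmt["GQ"])
                if has_gp and fmt.get("GP") is not None:
                    post[i, j] = np.asarray(fmt["GP"], dtype=float)
    calls = CallSet(genotypes=genotypes, gq=gq, posteriors=post)
    return calls, positions, alleles, snp_ids, sample_ids


# ---------------------------------------------------------------------------
# TSV schemas
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ["snp_id", "sample_id", "fragment_id", "mate_index", "base", "phred_qual"]
INTENSITY_COLUMNS = ["snp_id", "sample_id", "intensity_a", "intensity_b"]
CLUSTER_COLUMNS = [
    "snp_id", "class", "mean_a", "mean_b", "cov_aa", "cov_ab", "cov_bb", "prior",
]


def write_pileup_table(path, pileups: PileupSet) -> None:
    rows = []
    for key in sorted(pileups.pileups):
        p = pileups.pileups[key]
        for frag in p.fragments:
            for m, (base, qual) in enumerate(frag.observations):
                rows.append((p.snp_id, p.sample_id, frag.fragment_id, m, base, qual))
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileup_table(path, snp_ids, sample_ids, alleles) -> PileupSet:
    """Read the pileup TSV back against a known site/sample universe."""
    df = pd.read_csv(path, sep="\t", dtype={"base": str})
    _require_columns(df, PILEUP_COLUMNS, path)
    snp_index = {s: i for i, s in enumerate(snp_ids)}
    sample_index = {s: j for j, s in enumerate(sample_ids)}
    pileups: dict = {}
    grouped: dict = {}
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            i = snp_index[row.snp_id]
            j = sample_index[row.sample_id]
        except KeyError as exc:
            raise FormatError(f"{path}:{row_num}: unknown identifier {exc}") from exc
        grouped.setdefault((i, j), {}).setdefault(row.fragment_id, []).append(
            (row.base, int(row.phred_qual))
        )
    for (i, j), frags in grouped.items():
        ref, alt = alleles[i]
        pileups[(i, j)] = SitePileup(
            snp_ids[i],
            sample_ids[j],
            ref,
            alt,
            [FragmentObservation(fid, obs) for fid, obs in frags.items()],
        )
    return PileupSet(list(snp_ids), list(sample_ids), list(alleles), pileups)


def write_intensity_table(path, intensities: np.ndarray, snp_ids, sample_ids) -> None:
    """Long-format intensity TSV; missing entries get empty fields."""
    rows = []
    for i, sid in enumerate(snp_ids):
        for j, samp in enumerate(sample_ids):
            a, b = intensities[i, j]
            rows.append(
                (sid, samp, "" if np.isnan(a) else a, "" if np.isnan(b) else b)
            )
    pd.DataFrame(rows, columns=INTENSITY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_intensity_table(path, snp_ids=None, sample_ids=None):
    """Read the intensity TSV -> ((S, N, 2) array with NaN, snp_ids, sample_ids)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, INTENSITY_COLUMNS, path)
    if snp_ids is None:
        snp_ids = list(dict.fromkeys(df["snp_id"]))
    if sample_ids is None:
        sample_ids = list(dict.fromkeys(df["sample_id"]))
    snp_index = {s: i for i, s in enumerate(snp_ids)}
    sample_index = {s: j for j, s in enumerate(sample_ids)}
    out = np.full((len(snp_ids), len(sample_ids), 2), np.nan)
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            i = snp_index[row.snp_id]
            j = sample_index[row.sample_id]
        except KeyError as exc:
            raise FormatError(f"{path}:{row_num}: unknown identifier {exc}") from exc
        out[i, j, 0] = row.intensity_a if row.intensity_a == row.intensity_a else np.nan
        out[i, j, 1] = row.intensity_b if row.intensity_b == row.intensity_b else np.nan
    return out, snp_ids, sample_ids


def write_cluster_table(path, cluster_params: list, snp_ids) -> None:
    rows = []
    for sid, params in zip(snp_ids, cluster_params):
        for g in range(3):
            rows.append(
                (
                    sid, g,
                    params.means[g, 0], params.means[g, 1],
                    params.covs[g, 0, 0], params.covs[g, 0, 1], params.covs[g, 1, 1],
                    params.priors[g],
                )
            )
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cluster_table(path) -> tuple:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CLUSTER_COLUMNS, path)
    snp_ids = list(dict.fromkeys(df["snp_id"]))
    params = []
    for sid in snp_ids:
        sub = df[df["snp_id"] == sid].sort_values("class")
        if len(sub) != 3:
            raise FormatError(f"{path}: SNP {sid} does not have exactly 3 classes")
        means = sub[["mean_a", "mean_b"]].to_numpy()
        covs = np.zeros((3, 2, 2))
        covs[:, 0, 0] = sub["cov_aa"]
        covs[:, 0, 1] = covs[:, 1, 0] = sub["cov_ab"]
        covs[:, 1, 1] = sub["cov_bb"]
        params.append(ClusterParams(means, covs, sub["prior"].to_numpy()))
    return params, snp_ids


def write_covariate_table(path, covariates) -> None:
    covariates.to_csv(path, sep="\t", index_label="snp_id")


def read_covariate_table(path):
    return pd.read_csv(path, sep="\t", index_col="snp_id")


def read_bed_intervals(path) -> list:
    """BED intervals as (start, end), 0-based half-open; chrom ignored."""
    intervals = []
    with open(path) as fh:
        for line_num, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_num}: BED row needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{line_num}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{line_num}: end < start")
            intervals.append((start, end))
    return intervals


def _require_columns(df, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
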
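"""Per-SNP three-class bivariate-Gaussian mixture over array intensities.

Each SNP's two-channel probe intensities are modelled as a mixture of three
bivariate normals, one per genotype class g in {0, 1, 2} (non-reference
allele count), with class mean mu_g, covariance Sigma_g and mixing weight
pi_g. The module provides prior-anchored initialisation (a simplified stand
-in for Birdseed), per-sample class likelihoods, and the responsibility-
weighted M-step updates used by the outer EM.

Missing intensities (NaN rows) always yield flat likelihoods so the
naive-Bayes product with sequence likelihoods degrades gracefully.
"""

from __future__ import annotations

import numpy as np

from .containers import ClusterParams

#: Default covariance floor, as a fraction of the squared mean total intensity.
DEFAULT_COV_FLOOR_FRAC = 1e-4
#: Default prior pseudo-count.
DEFAULT_PSEUDO_COUNT = 0.1
#: Effective weight below which a component falls back to the template.
MIN_COMPONENT_WEIGHT = 0.5
#: Covariance inflation for empty components: a genotype class no sample is
#: believed to occupy keeps the template mean but with a covariance this many
#: times broader, expressing location uncertainty about a never-observed
#: cluster. Keeps the likelihood ratio against degenerate one-blob fits
#: bounded, so sequence evidence can overrule a failed probe.
EMPTY_COV_INFLATION = 25.0


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("intensity points must be an (n, 2) array")
    return pts


def _cov_floor(points: np.ndarray, frac: float = DEFAULT_COV_FLOOR_FRAC) -> float:
    finite = points[~np.isnan(points).any(axis=1)]
    if finite.size == 0:
        return frac
    total = float(np.abs(finite).sum(axis=1).mean())
    return max(frac * total**2, 1e-12)


def _floor_cov(cov: np.ndarray, eps: float) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w, eps)
    return (v * w) @ v.T


def _log_mvnorm_pdf(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log bivariate-normal density, vectorised over points."""
    diff = points - mean
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, diff.T)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (maha + logdet + 2.0 * np.log(2.0 * np.pi))


def _order_classes(params: ClusterParams) -> ClusterParams:
    # class index = non-ref allele count: contrast a - b decreasing in g
    contrast = params.means[:, 0] - params.means[:, 1]
    order = np.argsort(-contrast, kind="stable")
    return ClusterParams(
        params.means[order], params.covs[order], params.priors[order],
        params.uninformed,
    )


def intensity_genotype_likelihoods(
    point, params: ClusterParams
) -> np.ndarray:
    """Class-conditional densities P(y | g) for one intensity point.

    A missing point (any NaN) returns the flat triple (1, 1, 1).
    """
    y = np.asarray(point, dtype=float).reshape(2)
    if np.isnan(y).any():
        return np.ones(3)
    if not np.all(np.isfinite(y)):
        raise ValueError("intensity point must be finite or missing")
    out = np.empty(3)
    for g in range(3):
        out[g] = np.exp(_log_mvnorm_pdf(y[None, :], params.means[g], params.covs[g]))[0]
    return out


def log_likelihood_matrix(points, params: ClusterParams) -> np.ndarray:
    """(n, 3) log densities for many points; missing rows are 0 (flat)."""
    pts = _as_points(points)
    out = np.zeros((pts.shape[0], 3))
    ok = ~np.isnan(pts).any(axis=1)
    if ok.any():
        for g in range(3):
            out[ok, g] = _log_mvnorm_pdf(pts[ok], params.means[g], params.covs[g])
    return out


def mstep_update(
    points,
    responsibilities,
    prior_template: ClusterParams,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    cov_floor: float | None = None,
) -> ClusterParams:
    """Responsibility-weighted mean / covariance / mixing-weight update.

    mu_g is the responsibility-weighted average of the points, Sigma_g the
    weighted scatter about mu_g (eigenvalue-floored), and pi_g the weighted
    count plus a pseudo-count, renormalised. Classes whose effective weight
    is negligible keep the template's mean and covariance. Missing points are
    ignored. With no usable points the template is returned, flagged
    uninformed.
    """
    pts = _as_points(points)
    resp = np.asarray(responsibilities, dtype=float)
    if resp.shape != (pts.shape[0], 3):
        raise ValueError("responsibilities must be one triple per point")
    ok = ~np.isnan(pts).any(axis=1)
    pts, resp = pts[ok], resp[ok]
    if pts.shape[0] == 0:
        out = prior_template.copy()
        out.uninformed = True
        return out
    if cov_floor is None:
        cov_floor = _cov_floor(pts)

    n = pts.shape[0]
    weights = resp.sum(axis=0)  # (3,)
    priors = (weights + pseudo_count) / (n + 3 * pseudo_count)
    means = np.empty((3, 2))
    covs = np.empty((3, 2, 2))
    for g in range(3):
        if weights[g] < MIN_COMPONENT_WEIGHT:
            means[g] = prior_template.means[g]
            covs[g] = _floor_cov(
                prior_template.covs[g] * EMPTY_COV_INFLATION, cov_floor
            )
            continue
        means[g] = (resp[:, g : g + 1] * pts).sum(axis=0) / weights[g]
        diff = pts - means[g]
        covs[g] = (resp[:, g, None, None] * np.einsum("ni,nj->nij", diff, diff)).sum(
            axis=0
        ) / weights[g]
        covs[g] = _floor_cov(covs[g], cov_floor)
    return ClusterParams(means, covs, priors / priors.sum())


def init_clusters(
    points,
    prior_template: ClusterParams,
    n_iterations: int = 25,
    tol: float = 1e-8,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> tuple[ClusterParams, np.ndarray]:
    """Fit the per-SNP mixture by an internal EM anchored at template means.

    Components start at the prior template; classes are re-ordered after the
    fit so means are monotone along the allele-contrast (a - b) axis. Returns
    the fitted parameters and the per-iteration data log-likelihood trace
    (non-decreasing). With no non-missing points the template is returned
    unchanged, flagged uninformed.
    """
    pts = _as_points(points)
    ok = ~np.isnan(pts).any(axis=1)
    if not ok.any():
        out = prior_template.copy()
        out.uninformed = True
        return out, np.array([])
    obs = pts[ok]
    cov_floor = _cov_floor(obs)
    params = prior_template.copy()
    params.covs = np.stack([_floor_cov(c, cov_floor) for c in params.covs])

    trace = []
    for _ in range(max(1, n_iterations)):
        logdens = np.stack(
            [_log_mvnorm_pdf(obs, params.means[g], params.covs[g]) for g in range(3)],
            axis=1,
        )
        logw = logdens + np.log(params.priors)[None, :]
        m = logw.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logw - m).sum(axis=1))
        trace.append(float(lse.sum()))
        resp = np.exp(logw - lse[:, None])
        params = mstep_update(
            obs, resp, prior_template, pseudo_count=pseudo_count, cov_floor=cov_floor
        )
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            break
    return _order_classes(params), np.asarray(trace)
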
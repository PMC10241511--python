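"""Reconstruction-quality metrics and smoothing-effect profiling.

Reconstruction degree is the per-frame Pearson correlation between an
original cortical pattern and its model reconstruction, computed over the
analysis (non-medial) vertices.  Correlations are aggregated through
Fisher's z transform.  The implicit smoothing of a representation is
quantified by comparing its reconstructions against explicitly smoothed
copies of the original data over a grid of kernel widths: the FWHM at which
similarity peaks is the model's effective smoothing level.

Also here: covariate-adjusted (partial) correlations used for the
age/motion/brain-size analyses, and inter-session consistency (partial r and
ICC(2,1)) of subject-level scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CorticalTimeseries

__all__ = [
    "ReconstructionScore",
    "reconstruction_degree",
    "fisher_mean",
    "surface_smooth",
    "smoothing_profile",
    "adjusted_correlation",
    "intersession_consistency",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class ReconstructionScore:
    """Per-frame reconstruction degree plus the Fisher-aggregated summary."""

    per_frame_r: np.ndarray  # (T,), NaN where undefined
    subject_score: float
    model_tag: str = "model"


def reconstruction_degree(X: np.ndarray, X_rec: np.ndarray, mask=None) -> np.ndarray:
    """Pearson r between original and reconstructed pattern, per time point.

    ``mask`` selects the vertices entering the correlation (medial-wall and
    unassigned vertices are excluded upstream).  Frames where either pattern
    is constant have no defined correlation and are returned as NaN with a
    warning.
    """
    X = np.asarray(X, dtype=np.float64)
    X_rec = np.asarray(X_rec, dtype=np.float64)
    if X.shape != X_rec.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_rec.shape}")
    if mask is not None:
        X = X[np.asarray(mask)]
        X_rec = X_rec[np.asarray(mask)]
    a = X - X.mean(axis=0)
    b = X_rec - X_rec.mean(axis=0)
    sa = np.sqrt((a**2).sum(axis=0))
    sb = np.sqrt((b**2).sum(axis=0))
    ok = (sa > 0) & (sb > 0)
    r = np.full(X.shape[1], np.nan)
    r[ok] = np.clip((a[:, ok] * b[:, ok]).sum(axis=0) / (sa[ok] * sb[ok]),
                    -1.0, 1.0)
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} constant frame(s): correlation undefined, "
            "recorded as missing"
        )
    return r


def fisher_mean(r_values) -> float:
    """tanh(mean(atanh(r))): the Fisher-z average of correlations.

    Missing (NaN) values are skipped; values are clipped to +/-(1 - 1e-7)
    before the transform.  Lies between the minimum and maximum input and is
    monotone under elementwise increase.
    """
    r = np.asarray(r_values, dtype=np.float64).ravel()
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no defined correlations to average")
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    return float(np.tanh(z.mean()))


def score_reconstruction(X, X_rec, mask=None, model_tag="model") -> ReconstructionScore:
    """Convenience wrapper: per-frame r plus the Fisher-mean subject score."""
    r = reconstruction_degree(X, X_rec, mask=mask)
    return ReconstructionScore(per_frame_r=r, subject_score=fisher_mean(r),
                               model_tag=model_tag)


def surface_smooth(ts: CorticalTimeseries, mesh, fwhm_mm: float) -> CorticalTimeseries:
    """Geodesic Gaussian smoothing on the mesh; ``fwhm_mm=0`` is the identity.

    Kernel sd = fwhm / 2.355; geodesic distances are approximated by
    shortest paths along mesh edges.  The kernel is row-normalized, so a
    constant field is unchanged for any width.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return ts.replace()
    if ts.n_vertices != mesh.n_vertices:
        raise ValueError(
            f"timeseries has {ts.n_vertices} vertices, mesh has {mesh.n_vertices}")
    op = mesh.smoothing_operator(fwhm_mm)
    return ts.replace(values=op @ ts.values)


def smoothing_profile(X, X_rec, mesh, fwhm_grid=None, mask=None):
    """Similarity between a reconstruction and explicitly smoothed originals.

    For each FWHM in ``fwhm_grid`` (default 1..10 mm in 1 mm steps), computes
    the Fisher-mean per-frame correlation between ``X_rec`` and
    ``smooth(X, fwhm)``.  Returns ``(curve, effective_fwhm, at_boundary)``
    where ``effective_fwhm`` is the argmax of the curve and ``at_boundary``
    flags a peak at either end of the grid (the true peak may lie outside).
    """
    if fwhm_grid is None:
        fwhm_grid = np.arange(1.0, 11.0)
    fwhm_grid = np.asarray(fwhm_grid, dtype=np.float64)
    if fwhm_grid.size == 0 or np.any(np.diff(fwhm_grid) <= 0):
        raise ValueError("fwhm_grid must be non-empty and increasing")
    if mask is None:
        mask = getattr(mesh, "analysis_mask", None)
    ts = CorticalTimeseries(values=np.asarray(X, dtype=np.float64),
                            mesh_id=getattr(mesh, "mesh_id", "mesh"))
    curve = np.empty(fwhm_grid.size)
    for i, fwhm in enumerate(fwhm_grid):
        smoothed = surface_smooth(ts, mesh, fwhm)
        r = reconstruction_degree(smoothed.values, np.asarray(X_rec), mask=mask)
        curve[i] = fisher_mean(r)
    best = int(np.argmax(curve))
    at_boundary = best in (0, fwhm_grid.size - 1)
    return curve, float(fwhm_grid[best]), at_boundary


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residual of least-squares regression on covariates plus intercept."""
    n = len(y)
    design = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def adjusted_correlation(x, y, covariates=None):
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (with intercept); the
    correlation of the residuals is returned with a two-sided p-value from
    the t distribution on n - 2 - n_covariates degrees of freedom.  With no
    covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y lengths differ")
    n = len(x)
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
    n_cov = cov.shape[1]
    if n <= n_cov + 2:
        raise ValueError(f"need n > n_covariates + 2, got n={n}, k={n_cov}")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    # a variable perfectly explained by the covariates has no residual
    # association with anything: partial r is 0 by convention
    tol_x = 1e-12 * max((x - x.mean()) @ (x - x.mean()), 1e-300)
    tol_y = 1e-12 * max((y - y.mean()) @ (y - y.mean()), 1e-300)
    if (rx**2).sum() <= tol_x or (ry**2).sum() <= tol_y:
        return 0.0, 1.0
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    r = float((rx * ry).sum() / denom)
    df = n - 2 - n_cov
    r_t = np.clip(r, -_R_CLIP, _R_CLIP)
    t = r_t * np.sqrt(df / (1.0 - r_t**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def intersession_consistency(scores_s1, scores_s2, ages_s1, ages_s2):
    """Consistency of subject scores across two sessions, age-adjusted.

    Subjects must be paired (same order in both sessions).  Returns
    ``(partial_r, p, icc)`` where the partial correlation controls for age
    at each scan and the ICC is a two-way random-effects single-measure
    agreement coefficient, ICC(2,1), computed on age-residualized scores.
    """
    s1 = np.asarray(scores_s1, dtype=np.float64)
    s2 = np.asarray(scores_s2, dtype=np.float64)
    a1 = np.asarray(ages_s1, dtype=np.float64)
    a2 = np.asarray(ages_s2, dtype=np.float64)
    if not (s1.shape == s2.shape == a1.shape == a2.shape):
        raise ValueError("sessions must provide paired, equal-length inputs")
    n = len(s1)
    if n < 3:
        raise ValueError("need at least 3 paired subjects")

    # regress each session's scores on its own age at scan, then correlate
    r1 = _residualize(s1, a1[:, None]) if np.ptp(a1) > 0 else s1 - s1.mean()
    r2 = _residualize(s2, a2[:, None]) if np.ptp(a2) > 0 else s2 - s2.mean()
    denom = np.sqrt((r1**2).sum() * (r2**2).sum())
    if denom == 0:
        raise ValueError("zero-variance residual scores")
    partial_r = float((r1 * r2).sum() / denom)
    df = n - 3  # one covariate regressed from each side
    r_t = np.clip(partial_r, -_R_CLIP, _R_CLIP)
    tstat = r_t * np.sqrt(df / (1.0 - r_t**2))
    p = float(2.0 * stats.t.sf(abs(tstat), df))

    import pingouin as pg

    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "session": np.repeat(["s1", "s2"], n),
        "score": np.concatenate([r1, r2]),
    })
    icc_table = pg.intraclass_corr(data=long, targets="subject",
                                   raters="session", ratings="score"
                                   ).set_index("Type")
    # two-way random effects, absolute agreement, single measure: ICC(2,1),
    # labelled ICC(A,1) in McGraw-Wong notation by some pingouin versions
    for label in ("ICC2", "ICC(A,1)"):
        if label in icc_table.index:
            icc = float(icc_table.loc[label, "ICC"])
            break
    else:  # pragma: no cover - depends on pingouin version
        raise RuntimeError("ICC(2,1) row not found in pingouin output")
    return partial_r, p, icc
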
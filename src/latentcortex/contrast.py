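"""Age-related group differences in latent-space functional networks.

Per subject, the variance of each independent component's timecourse indexes
how strongly that network is engaged; correlating these variances with age
at scan (FDR-corrected across components) identifies maturing networks.  For
spatial contrasts the cohort is split into young / median / old groups
(default thresholds 39 and 43 postmenstrual weeks), each group's latent
basis for a component is estimated by dual regression, and group differences
are taken in the latent space before projection to the cortex through the
decoder — subtraction happens on latent vectors, not on maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .networks import CorticalMap, NetworkBasis, basis_to_cortex
from .vae import LatentTimeseries

__all__ = [
    "GroupSplit",
    "ic_variance",
    "variance_age_correlation",
    "split_age_groups",
    "dual_regression_basis",
    "group_network_map",
    "latent_difference_map",
]


@dataclass
class GroupSplit:
    """Index partition of a cohort into young / median / old groups."""

    young: np.ndarray
    median: np.ndarray
    old: np.ndarray
    threshold_low: float
    threshold_high: float


def _latent_mu(Z) -> np.ndarray:
    return Z.mu if isinstance(Z, LatentTimeseries) else np.asarray(Z, dtype=np.float64)


def ic_variance(Z_subject, W: np.ndarray) -> np.ndarray:
    """Sample variance of each component timecourse W @ mu_z for one subject."""
    mu = _latent_mu(Z_subject)
    if mu.shape[1] < 3:
        raise ValueError("need at least 3 frames to estimate variance")
    W = np.asarray(W, dtype=np.float64)
    series = W @ mu
    return series.var(axis=1, ddof=1)


def variance_age_correlation(variances: np.ndarray, ages, alpha: float = 0.05):
    """Correlate per-component timecourse variance with age across subjects.

    Benjamini-Hochberg FDR across components at ``alpha``.  Returns
    ``(r, p, significant)`` arrays of length n_components; zero-variance
    columns are excluded with a warning (NaN r, never significant).
    """
    V = np.asarray(variances, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if V.ndim != 2 or V.shape[0] != len(ages):
        raise ValueError("variances must be (n_subjects, n_components)")
    if len(ages) < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(ages) == 0:
        raise ValueError("constant ages: correlation undefined")
    Vc = V - V.mean(axis=0)
    ac = ages - ages.mean()
    sv = np.sqrt((Vc**2).sum(axis=0))
    ok = np.ptp(V, axis=0) > 0  # exact constant-column detection
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance component(s) excluded")
    n = len(ages)
    r = np.full(V.shape[1], np.nan)
    r[ok] = (Vc[:, ok] * ac[:, None]).sum(axis=0) / (sv[ok] * np.sqrt((ac**2).sum()))
    r_c = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    significant = np.zeros(V.shape[1], dtype=bool)
    if ok.any():
        significant[np.flatnonzero(ok)[
            multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]]] = True
    return r, p, significant


def split_age_groups(ages, low: float = 39.0, high: float = 43.0) -> GroupSplit:
    """Partition subjects into young (age <= low), old (age >= high), and
    median (the rest).  Warns if young or old comes back empty."""
    if low >= high:
        raise ValueError("low threshold must be below high threshold")
    ages = np.asarray(ages, dtype=np.float64)
    young = np.flatnonzero(ages <= low)
    old = np.flatnonzero(ages >= high)
    median = np.flatnonzero((ages > low) & (ages < high))
    if young.size == 0 or old.size == 0:
        warnings.warn("empty young or old group at the given thresholds")
    return GroupSplit(young=young, median=median, old=old,
                      threshold_low=low, threshold_high=high)


def dual_regression_basis(group_latents, basis: NetworkBasis,
                          component: int) -> np.ndarray:
    """Group latent basis for one component via dual regression.

    Stage 1: for every subject, ordinary least squares of the latent
    timeseries on that subject's component timecourses (W @ mu, each
    normalized to unit variance so that a subject's component amplitude is
    carried by the spatial weights, not the regressors).  Stage 2: the
    chosen component's weight vectors are averaged across the group.
    """
    if len(group_latents) == 0:
        raise ValueError("empty group")
    W = basis.unmixing
    weights = []
    for Z in group_latents:
        mu = _latent_mu(Z)
        Y = W @ (mu - basis.mean[:, None])  # (n_components, T)
        sd = Y.std(axis=1, ddof=1)
        Y = Y / np.where(sd > 0, sd, 1.0)[:, None]
        # stage-1 OLS: mu ~ Y  ->  B (k, n_components)
        B, *_ = np.linalg.lstsq(Y.T, mu.T, rcond=None)
        weights.append(B.T[:, component])
    return np.mean(weights, axis=0)


def group_network_map(group_latents, basis: NetworkBasis, component: int,
                      decoder, mapping=None, n_scales: int = 1000,
                      seed: int = 0) -> CorticalMap:
    """Cortical map of one component for a subject group (dual regression
    followed by decoder projection)."""
    b = dual_regression_basis(group_latents, basis, component)
    return basis_to_cortex(b, decoder, mapping, n_scales=n_scales, seed=seed)


def latent_difference_map(basisA: np.ndarray, basisB: np.ndarray, decoder,
                          mapping=None, n_scales: int = 1000,
                          seed: int = 0) -> CorticalMap:
    """Project a latent-space group difference to the cortex.

    The subtraction happens in latent space (d = basisA - basisB) before
    decoding, so the map reflects how the decoder renders the *difference*
    direction.  Antisymmetric under argument swap (exactly so for a fixed
    seed, since the same scaling factors are drawn).
    """
    a = np.asarray(basisA, dtype=np.float64).ravel()
    b = np.asarray(basisB, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("bases must share dimension")
    return basis_to_cortex(a - b, decoder, mapping, n_scales=n_scales, seed=seed)
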
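"""Synthetic two-hemisphere cortical meshes and surface-fMRI cohorts.

The generator is the desk-scale stand-in for restricted-access developmental
cohorts.  It produces, with a known ground truth: a spherical two-hemisphere
mesh, K smooth spatial networks, per-subject network timecourses whose
covariance varies linearly with age at scan, projection onto the mesh,
additive white noise, and per-vertex standardization.  Two acquisition
profiles emulate the main ways the real cohorts differ (frame count,
repetition time, noise level).

The :class:`SyntheticTruth` manifest (maps, age-effect slopes, noise level,
seed) is the recovery oracle for every downstream test: reconstruction,
age prediction, network mapping, and group contrasts are all checked against
quantities this module wrote down when it generated the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from . import _smooth
from .io import CorticalTimeseries, make_subject_table

__all__ = [
    "CorticalMesh",
    "SyntheticTruth",
    "make_mesh",
    "make_networks",
    "simulate_cohort",
    "default_truth",
    "COHORT_PROFILES",
]

#: Acquisition presets for the two emulated cohorts.  ``dhcp_like`` mimics a
#: fast multiband protocol (many frames, short TR, cleaner signal);
#: ``dbi_like`` a conventional protocol (few frames, long TR, noisier).
COHORT_PROFILES = {
    "dhcp_like": {"T": 1400, "tr_seconds": 0.392, "noise_sd": 0.04},
    "dbi_like": {"T": 150, "tr_seconds": 2.0, "noise_sd": 0.08},
}

#: AR(1) coefficient of network timecourses, mimicking BOLD temporal
#: autocorrelation (makes bandpass behaviour on synthetic data meaningful).
AR1_COEFFICIENT = 0.3

#: Fraction of vertices per hemisphere marked as medial wall (excluded from
#: correlations), taken nearest the pole that faces the other hemisphere.
MEDIAL_FRACTION = 0.05


@dataclass
class CorticalMesh:
    """Two-hemisphere triangulated sphere mesh.

    Vertices are ordered left-hemisphere block first, then right; the right
    hemisphere is a mirrored copy of the left.  ``medial_mask`` flags
    vertices excluded from analysis (the synthetic stand-in for the medial
    wall).
    """

    vertices: np.ndarray  # (V, 3) mm
    triangles: np.ndarray  # (F, 3) int
    hemisphere: np.ndarray  # (V,) 'L'/'R'
    medial_mask: np.ndarray  # (V,) bool
    mesh_id: str = "mesh"
    radius_mm: float = 40.0
    _smooth_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def analysis_mask(self) -> np.ndarray:
        """Boolean mask of non-medial (analysed) vertices."""
        return ~self.medial_mask

    def hemi_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def hemi_triangles(self, hemi: str) -> np.ndarray:
        """Triangles of one hemisphere, reindexed to that hemisphere's block."""
        idx = self.hemi_indices(hemi)
        lo, hi = idx.min(), idx.max()
        in_hemi = np.all((self.triangles >= lo) & (self.triangles <= hi), axis=1)
        return self.triangles[in_hemi] - lo

    def smoothing_operator(self, fwhm_mm: float):
        """Block-diagonal geodesic Gaussian smoothing matrix (cached)."""
        key = round(float(fwhm_mm), 6)
        if key not in self._smooth_cache:
            from scipy import sparse

            blocks = []
            for hemi in ("L", "R"):
                idx = self.hemi_indices(hemi)
                blocks.append(
                    _smooth.gaussian_operator(
                        self.vertices[idx], self.hemi_triangles(hemi), fwhm_mm
                    )
                )
            self._smooth_cache[key] = sparse.block_diag(blocks, format="csr")
        return self._smooth_cache[key]


def make_mesh(subdivisions: int = 3, radius_mm: float = 40.0) -> CorticalMesh:
    """Icosphere per hemisphere; the right hemisphere mirrors the left.

    Vertex/face counts follow the icosphere recurrence V = 10*4^s + 2,
    F = 20*4^s per hemisphere.  Hemisphere centres sit at x = -/+ 1.1*radius
    so the spheres do not intersect; each hemisphere's vertices lie on a
    sphere of ``radius_mm`` about its own centre.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    left_v = np.asarray(sphere.vertices, dtype=np.float64)
    left_t = np.asarray(sphere.faces, dtype=np.int64)
    offset = 1.1 * radius_mm

    # mirror in x and flip winding so normals stay outward
    right_v = left_v * np.array([-1.0, 1.0, 1.0])
    right_t = left_t[:, ::-1].copy()

    n = len(left_v)
    vertices = np.vstack([left_v + [-offset, 0, 0], right_v + [offset, 0, 0]])
    triangles = np.vstack([left_t, right_t + n])
    hemisphere = np.array(["L"] * n + ["R"] * n)

    # medial wall: vertices nearest the pole facing the other hemisphere
    n_medial = max(1, int(round(MEDIAL_FRACTION * n)))
    medial = np.zeros(2 * n, dtype=bool)
    inner_left = np.array([radius_mm, 0.0, 0.0])  # +x pole of the left sphere
    d_left = np.linalg.norm(left_v - inner_left, axis=1)
    medial[np.argsort(d_left, kind="stable")[:n_medial]] = True
    inner_right = np.array([-radius_mm, 0.0, 0.0])
    d_right = np.linalg.norm(right_v - inner_right, axis=1)
    medial[n + np.argsort(d_right, kind="stable")[:n_medial]] = True

    return CorticalMesh(
        vertices=vertices,
        triangles=triangles,
        hemisphere=hemisphere,
        medial_mask=medial,
        mesh_id=f"icosphere-s{subdivisions}-r{radius_mm:g}",
        radius_mm=radius_mm,
    )


def make_networks(
    mesh: CorticalMesh, K: int, smoothness_mm: float = 10.0, seed: int = 0
) -> np.ndarray:
    """K unit-norm smooth random spatial networks, one per row (K, V).

    Each map is white vertex noise passed through the mesh's geodesic
    Gaussian smoothing operator, then normalized to unit Euclidean norm.
    For moderate K the maps are mutually near-orthogonal because the sphere
    holds many independent smoothness-scale patches.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > mesh.n_vertices:
        raise ValueError(f"K={K} exceeds vertex count {mesh.n_vertices}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((K, mesh.n_vertices))
    smoothed = (mesh.smoothing_operator(smoothness_mm) @ noise.T).T
    return smoothed / np.linalg.norm(smoothed, axis=1, keepdims=True)


@dataclass
class SyntheticTruth:
    """Generator manifest: everything needed to re-create or score a cohort.

    The effective network covariance of a subject with age ``a`` (weeks) is
    ``base_cov + (a - age0) * age_effect`` where ``age0`` is the midpoint of
    ``age_range``.  Because the positive-semidefinite cone is convex and the
    covariance is linear in age, validity at both ends of ``age_range``
    guarantees validity at every age in between.
    """

    network_maps: np.ndarray  # (K, V), rows unit-norm
    base_cov: np.ndarray  # (K, K)
    age_effect: np.ndarray  # (K, K) slope of covariance per week
    noise_sd: float
    seed: int
    age_range: tuple = (24.29, 44.87)

    def __post_init__(self) -> None:
        self.network_maps = np.asarray(self.network_maps, dtype=np.float64)
        self.base_cov = np.asarray(self.base_cov, dtype=np.float64)
        self.age_effect = np.asarray(self.age_effect, dtype=np.float64)
        norms = np.linalg.norm(self.network_maps, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("network_maps rows must be unit-norm")
        for name, m in (("base_cov", self.base_cov), ("age_effect", self.age_effect)):
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        for age in self.age_range:
            cov = self.covariance_at(age)
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValueError(
                    f"effective covariance not PSD at age {age:.2f} weeks"
                )

    @property
    def n_networks(self) -> int:
        return self.network_maps.shape[0]

    @property
    def age0(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    def covariance_at(self, age_weeks: float) -> np.ndarray:
        return self.base_cov + (age_weeks - self.age0) * self.age_effect

    def to_json(self, path) -> None:
        payload = {
            "network_maps": self.network_maps.tolist(),
            "base_cov": self.base_cov.tolist(),
            "age_effect": self.age_effect.tolist(),
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "age_range": list(self.age_range),
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as f:
            payload = json.load(f)
        return cls(
            network_maps=np.array(payload["network_maps"]),
            base_cov=np.array(payload["base_cov"]),
            age_effect=np.array(payload["age_effect"]),
            noise_sd=payload["noise_sd"],
            seed=payload["seed"],
            age_range=tuple(payload["age_range"]),
        )


def default_truth(
    mesh: CorticalMesh,
    K: int = 5,
    seed: int = 0,
    noise_sd: float = 0.04,
    age_range: tuple = (24.29, 44.87),
    smoothness_mm: float = 10.0,
    effect_scale: float = 0.04,
) -> SyntheticTruth:
    """Study-default ground truth: K networks with a graded age effect.

    Baseline network covariance is identity plus a 0.2 coupling between the
    first two networks.  The age effect is a dense symmetric slope matrix —
    developmental change in functional connectivity is widespread rather than
    confined to a single edge — composed of a uniform positive drift on the
    couplings (connectivity predominantly strengthens with maturation) plus
    random per-pair variation, drawn once from ``seed`` and scaled so the
    largest-magnitude eigenvalue is ``effect_scale`` per week.  Because the
    half-width of the default age range is ~10 weeks, the covariance stays
    positive definite by construction (10.3 * effect_scale < the 0.8 smallest
    eigenvalue of the baseline).  The default magnitude puts
    chance-normalized age-prediction error around one half, a clear but not
    dominant developmental signal.
    """
    maps = make_networks(mesh, K, smoothness_mm=smoothness_mm, seed=seed)
    base = np.eye(K)
    base[0, 1] = base[1, 0] = 0.2
    rng = np.random.default_rng(seed + 202_301)
    raw = rng.standard_normal((K, K))
    sym = 0.5 * (raw + raw.T)
    sym /= np.abs(np.linalg.eigvalsh(sym)).max()
    if K > 1:
        drift = np.ones((K, K)) - np.eye(K)
        drift /= np.abs(np.linalg.eigvalsh(drift)).max()
        effect = 0.6 * drift + 0.4 * sym
    else:
        effect = sym
    effect *= effect_scale / np.abs(np.linalg.eigvalsh(effect)).max()
    return SyntheticTruth(
        network_maps=maps,
        base_cov=base,
        age_effect=effect,
        noise_sd=noise_sd,
        seed=seed,
        age_range=age_range,
    )


def _ar1_series(rng: np.random.Generator, cov: np.ndarray, T: int) -> np.ndarray:
    """Stationary Gaussian AR(1) (K, T) with marginal covariance ``cov``."""
    K = cov.shape[0]
    # eigen square root: robust to semidefinite covariances
    w, U = np.linalg.eigh(cov)
    L = U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    phi = AR1_COEFFICIENT
    innov_scale = np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal((K, T))
    s = np.empty((K, T))
    s[:, 0] = L @ eps[:, 0]
    for t in range(1, T):
        s[:, t] = phi * s[:, t - 1] + innov_scale * (L @ eps[:, t])
    return s


def simulate_cohort(
    mesh: CorticalMesh,
    truth: SyntheticTruth,
    n_subjects: int,
    T: int = 150,
    tr_seconds: float = 2.0,
    seed: int = 0,
    dataset_tag: str = "synthetic",
    standardize: bool = True,
):
    """Simulate a cohort of surface fMRI scans with known ground truth.

    Per subject: age drawn uniformly in ``truth.age_range``; network
    timecourses drawn as stationary AR(1) with marginal covariance
    ``truth.covariance_at(age)``; projected through ``truth.network_maps``;
    white vertex noise of sd ``truth.noise_sd`` added; each vertex series
    standardized (unless ``standardize=False``).  A synthetic framewise
    displacement series is attached for motion-selection tests.

    Returns
    -------
    scans : list of CorticalTimeseries
    table : pandas.DataFrame
        Subject table (one row per scan) with ages and dataset tags.
    manifest : dict
        All random draws needed to reproduce or score the cohort: ages and
        the per-subject child seeds.
    """
    from .io import normalize_timeseries

    rng = np.random.default_rng(seed)
    ages = rng.uniform(*truth.age_range, size=n_subjects)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)

    scans = []
    records = []
    for i in range(n_subjects):
        cov = truth.covariance_at(ages[i])
        eigmin = np.linalg.eigvalsh(cov).min()
        if eigmin < -1e-10:
            raise ValueError(
                f"network covariance not PSD at age {ages[i]:.2f} weeks "
                f"(min eigenvalue {eigmin:.3g})"
            )
        sub_rng = np.random.default_rng(child_seeds[i])
        s = _ar1_series(sub_rng, cov, T)  # (K, T)
        x = truth.network_maps.T @ s  # (V, T)
        if truth.noise_sd > 0:
            x = x + truth.noise_sd * sub_rng.standard_normal(x.shape)
        fd = np.abs(sub_rng.lognormal(mean=-2.2, sigma=0.6, size=T))
        ts = CorticalTimeseries(
            values=x,
            mesh_id=mesh.mesh_id,
            subject_id=f"sub-{i:04d}",
            session_id="ses-1",
            age_weeks=float(ages[i]),
            dataset_tag=dataset_tag,
            tr_seconds=tr_seconds,
            fd_series=fd,
        )
        if standardize:
            ts = normalize_timeseries(ts)
        scans.append(ts)
        records.append(
            {
                "subject_id": ts.subject_id,
                "session_id": ts.session_id,
                "age_weeks": ts.age_weeks,
                "dataset_tag": dataset_tag,
                "mean_fd": float(fd.mean()),
            }
        )

    table = make_subject_table(records)
    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "T": T,
        "tr_seconds": tr_seconds,
        "ages": ages.tolist(),
        "child_seeds": child_seeds.tolist(),
    }
    return scans, table, manifest
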